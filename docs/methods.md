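# Methods

## The analysis chain

swimnet implements a cross-sectional sportomics analysis over a two-sex
cohort of adolescent swimmers: (1) per-athlete critical-velocity estimation
from four exhaustive time trials; (2) per-metabolite sex comparison on a
normalised 32-species plasma panel; (3) Pearson correlation of metabolites
with performance variables, per sex; (4) a significance-thresholded
correlation network over the metabolites; (5) targeted eigenvector
centrality toward a metabolite of interest. The assumptions of each stage,
the tunable parameters, and the numerical choices are documented here.

## Critical velocity (distance–time model)

The model is the two-parameter linear relation D = CV·t + AWC, fit by OLS
with **distance as the response** — this is the direction in which the
model is stated, and slope/intercept then carry their physiological units
directly (CV in m/s, AWC in m). The t-on-D parameterisation is deliberately
not offered. All four distances {100, 200, 400, 800} m are required by
default; `require_all_distances=False` permits any ≥ 3 points for
robustness studies. A zero-variance time vector raises a degenerate-fit
error. R² is the squared Pearson correlation of D and t.

CV is reported in m/s throughout the library. Published summaries of this
protocol sometimes carry an m/min unit label, but times of ~75 s over 100 m
imply ~1 m/s, so m/s is the physically consistent unit; the report layer
can convert (`cv_unit="m/min"`) on request.

## Normalisation and group statistics

Normalisation is log10 then Pareto scaling: per variable,
x → (x − mean)/√s with s the n−1 sample SD of the logged values. Pareto
scaling is the standard metabolomics compromise between unit-variance
scaling and no scaling. Non-positive intensities are a hard domain error
(named by cell); a zero-variance variable is emitted as all zeros with a
warning record rather than NaN.

Sex comparison uses the two-sided **pooled-variance Student t** (not
Welch), chosen for consistency with the pooled-SD Cohen's d reported
alongside it:

    d = (mean_b − mean_a) / s_pooled,
    s_pooled² = ((n_a−1)s_a² + (n_b−1)s_b²) / (n_a+n_b−2)

d is computed signed and reported unsigned in effect-size tables. The
bands are small (0 ≤ |d| ≤ 0.5), medium (0.5 < |d| ≤ 0.8), large
(|d| > 0.8), with both boundaries inclusive downward. With printed summary
statistics for the 100-m trial (means 71.3/75.7, SDs 10.4/5.4, n 20/18)
this convention yields d = 0.52 where 0.53 is sometimes quoted; the
package reports what the arithmetic gives.

FDR control is Benjamini–Hochberg, by default over the joint 32-metabolite
family; `fdr_family="per-class"` corrects amino acids and acylcarnitines
separately (mirroring per-class figure panels). The q-values come from
statsmodels' step-up implementation and are verified in tests against
hand-computed step-up values.

Type-I error calibration of the pooled t (±0.01 of nominal 0.05 over
10,000 null simulations) is asserted in the acceptance tests.

## Correlations and the significance network

Pearson r with a two-sided p-value (the exact beta-form null, identical to
the t = r√((n−2)/(1−r²)) formulation, asserted to 1e−10 against an
explicit-sums oracle in tests). r is clamped to [−1, 1] against rounding
and p floored at the smallest positive normal double so perfect
correlations survive thresholding.

Network correlations are computed on the **log10 scale**: Pareto scaling is
an affine per-variable map, so Pearson r is invariant to it and only the
log transform matters. Edges are all pairs with p < α (α = 0.05 default),
with **no multiple-testing correction on edges** — the network is a
descriptive topology, not an inferential family — though BH on edges is
available as a sensitivity flag in the library. Nodes are the 32
metabolites only; metabolite–performance correlations live in a separate
table (per sex), with metabolites on the log10 scale and performance as
raw times (s) and fitted CV (m/s). Whether the network should be built on
the full cohort or one sex is genuinely ambiguous for this design; the
default is all athletes with a `subgroup` option rather than a guess.

## Targeted centrality

"Degree of proximity" of an edge to the target is formalised as
k = 1 + min over the edge's endpoints of the BFS hop distance to the
target: an edge touching the target is first-degree (k = 1), an edge whose
closer endpoint is one hop out is second-degree (k = 2), and so on. This
is the only reading consistent with the factor sequence 1, 0.5, 0.250,
0.125, 0.0625 for degrees 1–5. Beyond the fifth degree the geometric law
2^−(k−1) continues by default (the simplest consistent extension); a
`floor_at_fifth` flag clamps deeper edges at 0.0625 instead. Edge weight is
the factor times |r| — positive and inverse correlations are equally
treated; the sign is preserved as an edge attribute for reporting only.

Eigenvector centrality is computed by **power iteration authored in this
package** (library eigendecompositions appear only as test oracles):
uniform positive start, renormalised each step, convergence when the
max-abs difference between successive iterates is < tol (default 1e−10,
max_iter 1000). The computation is restricted to the target's connected
component; nodes outside it score exactly 0, and edges with an unreachable
endpoint are dropped with a record. On a connected nonnegative-weight
component Perron–Frobenius guarantees a unique positive principal
eigenvector.

A numerical subtlety: bipartite components (stars, paths, even cycles)
have symmetric spectra, so +λ and −λ tie in magnitude and plain power
iteration oscillates with period 2. The iteration therefore runs on
A + εI with ε = the maximum edge weight: a diagonal shift leaves every
eigenvector unchanged while making λ_max + ε strictly dominant, giving
fast unconditional convergence. (A vanishing shift such as 1e−12·max-weight
does *not* work: the magnitude gap it creates is of the same order, and
convergence would need ~10¹² iterations.) The reported eigenvalue is the
Rayleigh quotient on the unshifted matrix.

Scores are normalised to unit Euclidean norm over the component (the
common library convention; `norm="max"` offered for sensitivity, since
published centrality tables do not always state their normalisation).
The target participates in the eigenproblem but is excluded from the
influencer ranking; ties break by node label.

## Synthetic cohort generator

The generator defines the study conditions; it is not tuned per analysis.

* **Marginals** are lognormal — Gaussian on the log10 scale — matching the
  pipeline's log transform. Per-sex intensity means/SDs are converted to
  log10-normal parameters by moment matching, so configured intensity
  moments are reproduced exactly in expectation.
* **Defaults**: n = 20 male / 18 female; every metabolite 1.4 ± 0.25
  normalized intensity in both sexes except tyrosine (male 1.56 ± 0.22,
  female 1.30 ± 0.26) — tyrosine is the panel's single sex-dimorphic
  species, implying a pooled-SD d ≈ 1.08 between sexes.
* **Correlation structure** (log10 scale, shared by sexes): compound
  symmetry background — amino acids 0.10 among themselves, acylcarnitines
  0.20, cross-class 0.05 — with tyrosine's row overridden to a plausible
  biochemical sign pattern: tryptophan +0.66 (both aromatic, fed by the
  pentose-phosphate pathway), histidine +0.25, glycine −0.30, glutamine
  −0.28, arginine −0.25, free carnitine −0.25. The matrix is positive
  definite (smallest eigenvalue ≈ 0.009) and validated at config time;
  a non-PSD user matrix is rejected naming the offending eigenvalue.
  Only the tyrosine–tryptophan entry is anchored to a reported value; the
  rest of the matrix is a modelling choice exposed in config, not a claim
  about truth.
* **Performance**: per-athlete CV ~ N(1.01, 0.10²) m/s for males,
  N(1.00, 0.14²) for females; AWC ~ N(20, 8²) m for both (no published
  AWC summary exists for this protocol; 20 m is the OLS intercept implied
  by printed per-sex mean times, which give intercepts of 23–28 m).
  Times are t = (D − AWC)/CV, exactly linear before noise.
* **Tyrosine→time coupling (females only)**:
  Δt_d = c·(tyr − μ_tyr,female)·(d/100), default c = 25 s per intensity
  unit per 100 m. The shift is additive but distance-proportional: a
  constant additive shift would leave the D-on-t slope unchanged, whereas
  a distance-proportional one both slows every trial (positive time
  correlations) and lowers the fitted CV (negative CV correlation) while
  preserving exact linearity. The default magnitude produces female
  tyrosine–time correlations around r ≈ 0.3–0.5 at the default group
  sizes — detectable but not overwhelming, as in a small real cohort.
* **Noise**: multiplicative trial-time noise with CV 1%
  (`time_noise_cv = 0.01`), preserving per-athlete R² ≈ 0.99 .

What the generator does **not** emulate: analytical (MS) noise structure,
batch effects, missing values, menstrual-cycle dynamics in the female
metabolome, non-normal metabolite tails, or any dependence of performance
on metabolites other than tyrosine. Passing tests therefore demonstrate
that the pipeline's statistics and network machinery behave correctly
under the generative assumptions — not that the biological findings
themselves generalise.

## Problem sizes used in checks

Monte-Carlo parameter-recovery checks use n = 1000–5000 per sex (sampling
error on r at n = 5000 is ≈ 0.008, comfortably inside the ±0.05 bands);
null-calibration uses 10,000 replicates; eigenvector oracle equivalence
uses 200 random connected graphs of ≤ 10 nodes plus closed-form star and
path cases. The default study-condition cohort (20/18) is used everywhere
a realistic small-sample behaviour is the point.

## Known limitations

* The centrality ranking on a small cohort's network is noisy: with 38
  edges estimated from 38 athletes, edge membership near p = 0.05 is
  unstable, and the ranking inherits that instability. The package
  deliberately reports it anyway — the method is descriptive.
* The pooled t assumes equal group variances; with the default generator
  this holds by construction except for tyrosine's modestly different SDs.
* Partial correlations, graphical models, bootstrap confidence intervals
  on centrality, and multivariate discrimination (PCA/PLS-DA/random
  forest) are out of scope.
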