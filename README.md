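# swimnet

Analysis pipeline linking plasma amino acids and acylcarnitines to the
performance of adolescent swimmers: critical-velocity estimation from time
trials, sex-group metabolite statistics, and a **targeted correlation
network** that ranks metabolites by their influence toward a metabolite of
interest (tyrosine) via proximity-weighted eigenvector centrality.

It is written for exercise physiologists and sportomics researchers who have
a targeted metabolomics panel (here 20 amino acids + 12 acylcarnitines,
normalized intensities) and a set of exhaustive time trials per athlete, and
want a reproducible, tested implementation of this analysis chain. Because
cohort data of this kind is rarely deposited, the package ships a synthetic
cohort generator that emulates the statistical structure the analysis
assumes, so every stage is testable without any download.

## The models

**Critical velocity.** For each athlete the four trial distances
D ∈ {100, 200, 400, 800} m and times t are fit by ordinary least squares as

    D = CV·t + AWC

where the slope CV (m/s) is the critical velocity — the highest sustainable
swimming velocity — and the intercept AWC (m) is a finite anaerobic work
reserve. R² of the fit indicates the reliability of the linear adjustment
(~0.99 in trained swimmers).

**Group statistics.** Metabolite intensities are log10-transformed and
Pareto-scaled (x → (x − x̄)/√s). Sexes are compared per variable with the
pooled-variance Student t-test, Benjamini–Hochberg FDR over the panel, and
pooled-SD Cohen's d, classed small (|d| ≤ 0.5), medium (0.5 < |d| ≤ 0.8) or
large (|d| > 0.8).

**Targeted network.** Metabolite pairs whose Pearson correlation has
p < 0.05 form an undirected graph. With a target node T (tyrosine), every
edge (u, v) gets the weight

    w(u,v) = 2^−(k−1) · |r(u,v)|,   k = 1 + min(hop(u,T), hop(v,T))

so a first-degree edge (touching T) keeps |r|, a second-degree edge keeps
|r|/2, then 0.250·|r|, 0.125·|r|, 0.0625·|r|, … Positive and inverse
correlations are treated alike. Node importance is the principal eigenvector
x of the weighted adjacency A (Ax = λx, computed by power iteration on T's
connected component, unit Euclidean norm); non-target nodes sorted by score
are the metabolites most influential in reaching T.

## Worked example

Run the numbered analysis drivers (each writes tables under `results/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_fit_critical_velocity.py
python analysis/03_group_statistics.py
python analysis/04_correlation_network.py
python analysis/05_targeted_centrality.py
```

The simulated cohort (20 male / 18 female) gives, among other output:

```
female: CV 1.02 ± 0.16 m/s, AWC 21.7 ± 6.6 m, R² 1.000 ± 0.000
  male: CV 0.99 ± 0.08 m/s, AWC 20.1 ± 11.7 m, R² 1.000 ± 0.000

     cv: male 0.99 ± 0.08 vs female 1.02 ± 0.16 [m/s]  ES = 0.30 (small), p = 0.360

female tyrosine vs performance:
  t400: r = +0.50, p = 0.033 *
  t800: r = +0.54, p = 0.020 *
    cv: r = -0.51, p = 0.029 *

network: 32 nodes, 38 edges at p < 0.05
most influential nodes toward tyrosine:
  tryptophan: 0.326
  myristoylcarnitine: 0.308
```

Reading: the distance–time relation is near-perfectly linear per athlete
(R² ≈ 1.0); performance differs little between sexes (all effect sizes
small); in females, higher plasma tyrosine goes with slower trial times
(positive r) and a lower critical velocity (negative r) — exactly the
coupling the generator injects; and the centrality ranking names the
metabolites whose correlation structure most strongly reaches tyrosine in
this particular simulated cohort (scores are eigenvector entries under unit
Euclidean norm, printed to 3 decimals). At n = 20/18 a chance co-discovery
in the group statistics (here leucine) is expected behaviour, not a bug.

The same stages are available as a CLI (`swimnet simulate | fit-cv |
group-stats | network | target-centrality | run`) and as library functions.

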