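"""Synthetic swimmer cohorts with a realistic metabolite/performance structure.

The generator emulates a two-sex adolescent swimming cohort: a 32-metabolite
plasma panel (20 amino acids, 12 acylcarnitines) drawn from a multivariate
lognormal with a configurable between-metabolite correlation structure on the
log10 scale, and four exhaustive time trials (100/200/400/800 m) built from a
per-athlete linear distance--time relationship D = CV.t + AWC with small
multiplicative timing noise.  In females only, an optional tyrosine-dependent
shift slows times in proportion to distance, producing the positive
tyrosine--time and negative tyrosine--CV couplings the downstream correlation
analysis is designed to detect.

All randomness flows through a single :class:`numpy.random.Generator` seeded
explicitly, so cohorts are reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AMINO_ACIDS",
    "ACYLCARNITINES",
    "METABOLITES",
    "DISTANCES_M",
    "SEXES",
    "ConfigError",
    "CohortParseError",
    "GeneratorConfig",
    "Athlete",
    "Cohort",
    "default_base_correlation",
    "default_config",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: The 20 proteinogenic amino acids quantified in the plasma panel.
AMINO_ACIDS: tuple[str, ...] = (
    "alanine",
    "arginine",
    "asparagine",
    "aspartate",
    "cysteine",
    "glutamate",
    "glutamine",
    "glycine",
    "histidine",
    "isoleucine",
    "leucine",
    "lysine",
    "methionine",
    "phenylalanine",
    "proline",
    "serine",
    "threonine",
    "tryptophan",
    "tyrosine",
    "valine",
)

#: Twelve acylcarnitine species, free carnitine (C0) through C18.
ACYLCARNITINES: tuple[str, ...] = (
    "free_carnitine",
    "acetylcarnitine",
    "propionylcarnitine",
    "butyrylcarnitine",
    "isovalerylcarnitine",
    "hexanoylcarnitine",
    "octanoylcarnitine",
    "decanoylcarnitine",
    "dodecanoylcarnitine",
    "myristoylcarnitine",
    "palmitoylcarnitine",
    "stearoylcarnitine",
)

METABOLITES: tuple[str, ...] = AMINO_ACIDS + ACYLCARNITINES

DISTANCES_M: tuple[int, ...] = (100, 200, 400, 800)
TIME_COLUMNS: tuple[str, ...] = tuple(f"t{d}" for d in DISTANCES_M)

SEXES: tuple[str, ...] = ("male", "female")


class ConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


class CohortParseError(ValueError):
    """Raised when a cohort CSV cannot be parsed; names the offending cell."""


def default_base_correlation(names: Sequence[str] = METABOLITES) -> np.ndarray:
    """Default between-metabolite correlation matrix on the log10 scale.

    Compound-symmetry background (amino acids 0.10 among themselves,
    acylcarnitines 0.20, cross-class 0.05) with tyrosine's row overridden to
    the qualitative sign pattern observed around tyrosine in adolescent
    swimmers: a strong positive tie to tryptophan (0.66, both aromatic amino
    acids fed by the pentose-phosphate pathway), positive histidine, and
    inverse glycine/glutamine/arginine/free-carnitine couplings.  The matrix
    is positive definite (smallest eigenvalue ~0.009).
    """
    names = list(names)
    n = len(names)
    idx = {m: i for i, m in enumerate(names)}
    n_aa = sum(1 for m in names if m in AMINO_ACIDS)
    corr = np.full((n, n), 0.05)
    corr[:n_aa, :n_aa] = 0.10
    corr[n_aa:, n_aa:] = 0.20
    np.fill_diagonal(corr, 1.0)
    if "tyrosine" in idx:
        tyr = idx["tyrosine"]
        for partner, r in (
            ("tryptophan", 0.66),
            ("glycine", -0.30),
            ("glutamine", -0.28),
            ("arginine", -0.25),
            ("histidine", 0.25),
            ("free_carnitine", -0.25),
        ):
            if partner in idx:
                corr[tyr, idx[partner]] = corr[idx[partner], tyr] = r
    return corr


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Metabolite means and SDs are given on the normalized-intensity scale
    (the scale on which group summaries are reported); internally they are
    converted to log10-normal parameters by moment matching so that the
    sampled intensity mean/SD reproduce the configured values.

    Parameters
    ----------
    n_male, n_female
        Group sizes; defaults 20/18 match a regional adolescent cohort.
    metabolite_names
        Panel labels, canonical order (20 amino acids then 12 acylcarnitines).
    mean_intensity, sd_intensity
        Per-sex, per-metabolite normalized-intensity mean and SD.  The default
        sets every metabolite to 1.4 +/- 0.25 in both sexes except tyrosine
        (male 1.56 +/- 0.22, female 1.30 +/- 0.26), the panel's single
        sex-dimorphic species.
    base_correlation
        Symmetric positive-semidefinite correlation matrix on the log10 scale
        shared by both sexes; see :func:`default_base_correlation`.
    tyrosine_time_coupling_female
        Signed coefficient c of the female-only trial-time shift
        ``dt_d = c * (tyr - mean_tyr_female) * d / 100`` in seconds per
        normalized-intensity unit per 100 m.  Distance-proportional so that a
        positive c both slows every trial and lowers the fitted critical
        velocity, while leaving distance exactly linear in time.
    cv_mean, cv_sd
        Per-sex critical velocity distribution (m/s); defaults
        male 1.01 +/- 0.10, female 1.00 +/- 0.14.
    awc_mean, awc_sd
        Anaerobic work capacity distribution, metres (intercept of the
        distance--time line); default 20 +/- 8 m.
    time_noise_cv
        Fractional SD of multiplicative trial-time noise; default 0.01 keeps
        per-athlete R^2 of the distance--time fit around 0.99.
    seed
        Default RNG seed; ``generate_cohort(config, seed=...)`` overrides it.
    """

    n_male: int = 20
    n_female: int = 18
    metabolite_names: tuple[str, ...] = METABOLITES
    mean_intensity: dict[str, dict[str, float]] = field(default_factory=dict)
    sd_intensity: dict[str, dict[str, float]] = field(default_factory=dict)
    base_correlation: np.ndarray | None = None
    tyrosine_time_coupling_female: float = 25.0
    cv_mean: dict[str, float] = field(
        default_factory=lambda: {"male": 1.01, "female": 1.00}
    )
    cv_sd: dict[str, float] = field(
        default_factory=lambda: {"male": 0.10, "female": 0.14}
    )
    awc_mean: float = 20.0
    awc_sd: float = 8.0
    time_noise_cv: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.metabolite_names = tuple(self.metabolite_names)
        if not self.mean_intensity:
            self.mean_intensity = {
                sex: {m: 1.4 for m in self.metabolite_names} for sex in SEXES
            }
            if "tyrosine" in self.metabolite_names:
                self.mean_intensity["male"]["tyrosine"] = 1.56
                self.mean_intensity["female"]["tyrosine"] = 1.30
        if not self.sd_intensity:
            self.sd_intensity = {
                sex: {m: 0.25 for m in self.metabolite_names} for sex in SEXES
            }
            if "tyrosine" in self.metabolite_names:
                self.sd_intensity["male"]["tyrosine"] = 0.22
                self.sd_intensity["female"]["tyrosine"] = 0.26
        if self.base_correlation is None:
            self.base_correlation = default_base_correlation(self.metabolite_names)
        self.base_correlation = np.asarray(self.base_correlation, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_male < 2 or self.n_female < 2:
            raise ConfigError(
                f"need at least 2 athletes per sex, got n_male={self.n_male}, "
                f"n_female={self.n_female}"
            )
        if self.time_noise_cv < 0:
            raise ConfigError(f"time_noise_cv must be >= 0, got {self.time_noise_cv}")
        for sex in SEXES:
            if self.cv_sd[sex] <= 0:
                raise ConfigError(f"cv_sd[{sex}] must be > 0, got {self.cv_sd[sex]}")
            for m in self.metabolite_names:
                if self.sd_intensity[sex][m] <= 0:
                    raise ConfigError(
                        f"sd_intensity[{sex}][{m}] must be > 0, "
                        f"got {self.sd_intensity[sex][m]}"
                    )
        if self.awc_sd <= 0:
            raise ConfigError(f"awc_sd must be > 0, got {self.awc_sd}")
        corr = self.base_correlation
        k = len(self.metabolite_names)
        if corr.shape != (k, k):
            raise ConfigError(
                f"base_correlation shape {corr.shape} != ({k}, {k})"
            )
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ConfigError("base_correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ConfigError("base_correlation must have a unit diagonal")
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < -1e-10:
            raise ConfigError(
                "base_correlation is not positive semidefinite: "
                f"smallest eigenvalue {eigvals.min():.3e}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        """Load a config from a YAML (or JSON) mapping of field overrides."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "base_correlation" in raw and raw["base_correlation"] is not None:
            raw["base_correlation"] = np.asarray(raw["base_correlation"], dtype=float)
        return cls(**raw)


def default_config(**overrides) -> GeneratorConfig:
    """The study-condition configuration (n = 20 male / 18 female)."""
    return GeneratorConfig(**overrides)


@dataclass
class Athlete:
    id: str
    sex: str
    times_s: dict[int, float]
    metabolites: dict[str, float]


@dataclass
class Cohort:
    """A swimming cohort: per-athlete sex, trial times, metabolite panel."""

    athletes: list[Athlete]
    metabolite_names: tuple[str, ...] = METABOLITES

    def __len__(self) -> int:
        return len(self.athletes)

    def sexes(self) -> list[str]:
        return [a.sex for a in self.athletes]

    def subgroup(self, sex: str) -> "Cohort":
        if sex == "all":
            return self
        return Cohort(
            [a for a in self.athletes if a.sex == sex], self.metabolite_names
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.athletes:
            row: dict[str, object] = {"id": a.id, "sex": a.sex}
            for d in DISTANCES_M:
                row[f"t{d}"] = a.times_s[d]
            for m in self.metabolite_names:
                row[m] = a.metabolites[m]
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, metabolite_names: Sequence[str] = METABOLITES
    ) -> "Cohort":
        athletes = []
        for i, rec in frame.iterrows():
            athletes.append(
                Athlete(
                    id=str(rec["id"]),
                    sex=str(rec["sex"]),
                    times_s={d: float(rec[f"t{d}"]) for d in DISTANCES_M},
                    metabolites={m: float(rec[m]) for m in metabolite_names},
                )
            )
        return cls(athletes, tuple(metabolite_names))

    def validate(self) -> None:
        for a in self.athletes:
            times = [a.times_s[d] for d in DISTANCES_M]
            if any(t <= 0 for t in times):
                raise ValueError(f"athlete {a.id}: non-positive trial time")
            if not all(t1 < t2 for t1, t2 in zip(times, times[1:])):
                raise ValueError(
                    f"athlete {a.id}: times not strictly increasing with distance"
                )
            for m in self.metabolite_names:
                if not (a.metabolites[m] > 0):
                    raise ValueError(
                        f"athlete {a.id}: metabolite {m} intensity "
                        f"{a.metabolites[m]} is not > 0 (log10 undefined)"
                    )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """log10-normal (mu, sigma) whose intensity mean/SD match the arguments."""
    var_ln = math.log1p((sd / mean) ** 2)
    mu_ln = math.log(mean) - var_ln / 2.0
    ln10 = math.log(10.0)
    return mu_ln / ln10, math.sqrt(var_ln) / ln10


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> Cohort:
    """Draw a synthetic cohort; deterministic for a fixed config and seed.

    Metabolites are sampled from a multivariate normal on the log10 scale
    (sex-specific moment-matched means/SDs, shared correlation matrix) and
    exponentiated.  Trial times are built from per-athlete draws of CV and AWC
    as t = (D - AWC)/CV, shifted in females by the tyrosine coupling, then
    perturbed with multiplicative noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    names = config.metabolite_names
    k = len(names)

    # Cholesky with a tiny jitter fallback for exactly-singular PSD inputs.
    corr = config.base_correlation
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(k))

    tyr_mean_f = config.mean_intensity["female"].get("tyrosine")

    athletes: list[Athlete] = []
    counter = 1
    for sex, n in (("male", config.n_male), ("female", config.n_female)):
        mu = np.empty(k)
        sig = np.empty(k)
        for j, m in enumerate(names):
            mu[j], sig[j] = _lognormal_params(
                config.mean_intensity[sex][m], config.sd_intensity[sex][m]
            )
        z = rng.standard_normal((n, k)) @ chol.T
        log_intens = mu + sig * z
        intens = np.power(10.0, log_intens)

        cv = rng.normal(config.cv_mean[sex], config.cv_sd[sex], size=n)
        # guard against non-physical draws under extreme configs
        while (cv <= 0.1).any():
            bad = cv <= 0.1
            cv[bad] = rng.normal(config.cv_mean[sex], config.cv_sd[sex], bad.sum())
        awc = rng.normal(config.awc_mean, config.awc_sd, size=n)

        noise = rng.normal(0.0, 1.0, size=(n, len(DISTANCES_M)))
        for i in range(n):
            metab = {m: float(intens[i, j]) for j, m in enumerate(names)}
            times: dict[int, float] = {}
            for di, d in enumerate(DISTANCES_M):
                t = (d - awc[i]) / cv[i]
                if sex == "female" and tyr_mean_f is not None:
                    t += (
                        config.tyrosine_time_coupling_female
                        * (metab["tyrosine"] - tyr_mean_f)
                        * d
                        / 100.0
                    )
                t *= 1.0 + config.time_noise_cv * noise[i, di]
                times[d] = float(t)
            athletes.append(
                Athlete(
                    id=f"{'M' if sex == 'male' else 'F'}{counter:03d}",
                    sex=sex,
                    times_s=times,
                    metabolites=metab,
                )
            )
            counter += 1

    cohort = Cohort(athletes, names)
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort as UTF-8 CSV: id, sex, t100..t800, 32 metabolites."""
    frame = cohort.to_frame()
    frame.to_csv(path, index=False, float_format="%.12g")


def read_cohort(
    path: str | Path, metabolite_names: Sequence[str] = METABOLITES
) -> Cohort:
    """Read a cohort CSV, validating schema, sex labels and positivity.

    Raises :class:`CohortParseError` naming the offending row/column on any
    missing column, unknown sex label, non-numeric cell, or non-positive
    metabolite intensity.
    """
    frame = pd.read_csv(path, dtype=str)
    expected = ["id", "sex", *TIME_COLUMNS, *metabolite_names]
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise CohortParseError(f"{path}: missing column(s) {missing}")

    numeric_cols = [*TIME_COLUMNS, *metabolite_names]
    athletes: list[Athlete] = []
    for i, rec in frame.iterrows():
        sex = str(rec["sex"]).strip().lower()
        if sex not in SEXES:
            raise CohortParseError(
                f"{path}: row {i}, column 'sex': unknown label {rec['sex']!r} "
                f"(expected one of {SEXES})"
            )
        values: dict[str, float] = {}
        for col in numeric_cols:
            try:
                values[col] = float(rec[col])
            except (TypeError, ValueError):
                raise CohortParseError(
                    f"{path}: row {i}, column '{col}': non-numeric cell "
                    f"{rec[col]!r}"
                ) from None
        for m in metabolite_names:
            if not (values[m] > 0):
                raise CohortParseError(
                    f"{path}: row {i}, column '{m}': intensity {values[m]} "
                    "is not > 0 (log10 undefined)"
                )
        athletes.append(
            Athlete(
                id=str(rec["id"]),
                sex=sex,
                times_s={d: values[f"t{d}"] for d in DISTANCES_M},
                metabolites={m: values[m] for m in metabolite_names},
            )
        )
    return Cohort(athletes, tuple(metabolite_names))
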