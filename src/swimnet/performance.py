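"""Critical velocity and anaerobic work capacity from swim time trials.

The distance--time model is the two-parameter linear relation

    D = CV * t + AWC

fitted per athlete by ordinary least squares of distance on time over the
four exhaustive trials (100/200/400/800 m).  The slope CV (m/s) is the
highest sustainable velocity; the intercept AWC (m) a finite work reserve
available above it.  R^2 of the fit indicates the reliability of the linear
adjustment (typically > 0.99 in trained swimmers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from swimnet.cohort import DISTANCES_M, Cohort
from swimnet import stats as mstats

__all__ = [
    "CVFit",
    "DegenerateFitError",
    "InsufficientGroupError",
    "fit_cv",
    "fit_cohort",
    "summarize_group_performance",
]


class DegenerateFitError(ValueError):
    """Raised when the trial times carry no variance to regress on."""


class InsufficientGroupError(ValueError):
    """Raised when a sex group is too small for a comparison."""


@dataclass(frozen=True)
class CVFit:
    """Result of one athlete's distance--time regression."""

    cv: float  # slope, m/s
    awc: float  # intercept, m
    r_squared: float


def _as_pairs(trials) -> list[tuple[float, float]]:
    if isinstance(trials, Mapping):
        return [(float(d), float(t)) for d, t in sorted(trials.items())]
    return [(float(d), float(t)) for d, t in trials]


def fit_cv(
    trials: Mapping[int, float] | Iterable[tuple[float, float]],
    require_all_distances: bool = True,
) -> CVFit:
    """OLS fit of distance on time: slope = CV (m/s), intercept = AWC (m).

    Parameters
    ----------
    trials
        Mapping distance (m) -> time (s), or iterable of (distance, time)
        pairs.  By default the full set {100, 200, 400, 800} m is required;
        pass ``require_all_distances=False`` to fit any >= 3 points.
    """
    pairs = _as_pairs(trials)
    if require_all_distances:
        got = {int(d) for d, _ in pairs}
        if got != set(DISTANCES_M):
            raise ValueError(
                f"expected distances {set(DISTANCES_M)}, got {sorted(got)}; "
                "pass require_all_distances=False to fit a subset"
            )
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 trials, got {len(pairs)}")
    dist = np.array([d for d, _ in pairs])
    time = np.array([t for _, t in pairs])
    if (time <= 0).any():
        raise ValueError("all trial times must be > 0")
    if np.ptp(time) == 0:
        raise DegenerateFitError("zero variance in trial times; cannot fit CV")
    res = sp_stats.linregress(time, dist)
    return CVFit(cv=float(res.slope), awc=float(res.intercept),
                 r_squared=float(res.rvalue ** 2))


def fit_cohort(cohort: Cohort) -> pd.DataFrame:
    """Per-athlete CV table: id, sex, cv_mps, awc_m, r_squared."""
    rows = [
        {"id": a.id, "sex": a.sex, **_fit_row(a.times_s)} for a in cohort.athletes
    ]
    return pd.DataFrame(rows, columns=["id", "sex", "cv_mps", "awc_m", "r_squared"])


def _fit_row(times: Mapping[int, float]) -> dict[str, float]:
    fit = fit_cv(times)
    return {"cv_mps": fit.cv, "awc_m": fit.awc, "r_squared": fit.r_squared}


def summarize_group_performance(cohort: Cohort) -> pd.DataFrame:
    """Per-sex mean/SD and effect size for each trial distance and for CV.

    Returns one row per performance variable (t100..t800 in seconds, cv in
    m/s) with male/female n, mean, SD, pooled-t statistics and Cohen's d
    with its small/medium/large class.
    """
    by_sex = {s: cohort.subgroup(s) for s in ("male", "female")}
    for s, sub in by_sex.items():
        if len(sub) < 2:
            raise InsufficientGroupError(
                f"sex group '{s}' has {len(sub)} athletes; need >= 2"
            )
    cv_tables = {s: fit_cohort(sub) for s, sub in by_sex.items()}

    rows = []
    for d in DISTANCES_M:
        male = np.array([a.times_s[d] for a in by_sex["male"].athletes])
        female = np.array([a.times_s[d] for a in by_sex["female"].athletes])
        rows.append(_summary_row(f"t{d}", "s", male, female))
    male_cv = cv_tables["male"]["cv_mps"].to_numpy()
    female_cv = cv_tables["female"]["cv_mps"].to_numpy()
    rows.append(_summary_row("cv", "m/s", male_cv, female_cv))
    return pd.DataFrame(rows)


def _summary_row(name: str, unit: str, male: np.ndarray, female: np.ndarray) -> dict:
    comp = mstats.group_compare(male, female, variable=name)
    return {
        "variable": name,
        "unit": unit,
        "n_male": len(male),
        "mean_male": comp.mean_a,
        "sd_male": comp.sd_a,
        "n_female": len(female),
        "mean_female": comp.mean_b,
        "sd_female": comp.sd_b,
        "t_stat": comp.t_stat,
        "p_value": comp.p_value,
        "d": abs(comp.d),
        "d_class": comp.d_class,
    }
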