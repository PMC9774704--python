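"""Pearson significance networks over the metabolite panel.

Every metabolite pair gets a sample Pearson r with a two-sided p-value from
the exact null distribution of r under bivariate normality (equivalently the
t = r*sqrt((n-2)/(1-r^2)) form on n-2 degrees of freedom).  Pairs with
p < alpha become edges of an undirected significance graph whose nodes are
the metabolites; correlations with the performance variables (trial times
and critical velocity) are kept in a separate table rather than entering the
network.

Correlations are computed on the log10 scale; the Pareto scaling step is an
affine per-variable map and leaves Pearson r unchanged, so network results
are identical on log10 and log-Pareto data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from swimnet.cohort import DISTANCES_M, Cohort
from swimnet.performance import fit_cohort
from swimnet.stats import Panel, log_pareto, panel_from_cohort

__all__ = [
    "CorrelationMatrix",
    "pearson_with_p",
    "correlation_matrix",
    "build_network",
    "performance_correlations",
    "significance_graph_from_edges",
    "write_edge_list",
    "read_edge_list",
]

_P_FLOOR = float(np.finfo(float).tiny)


@dataclass
class CorrelationMatrix:
    """Symmetric r and two-sided p matrices plus the common sample count."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int
    excluded: tuple[str, ...] = ()  # constant variables dropped with warning


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Sample Pearson r with two-sided p-value and the sample count.

    r is clamped to [-1, 1] against floating-point rounding and p floored at
    the smallest positive normal double so that perfectly correlated pairs
    survive downstream log/threshold operations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = sp_stats.pearsonr(x, y)
    r = float(min(1.0, max(-1.0, res.statistic)))
    p = float(max(res.pvalue, _P_FLOOR))
    return r, p, n


def correlation_matrix(data: Panel | pd.DataFrame) -> CorrelationMatrix:
    """All-pairs Pearson r and p over the columns of a panel.

    Constant variables cannot be correlated; they are excluded with a record
    in ``excluded`` rather than raising.
    """
    frame = data.data if isinstance(data, Panel) else data
    if len(frame) < 3:
        raise ValueError(f"need >= 3 rows, got {len(frame)}")
    values = frame.astype(float)
    constant = [c for c in values.columns if np.ptp(values[c].to_numpy()) == 0]
    kept = [c for c in values.columns if c not in constant]
    r = pd.DataFrame(np.eye(len(kept)), index=kept, columns=kept)
    p = pd.DataFrame(np.nan, index=kept, columns=kept)
    for i, u in enumerate(kept):
        for v in kept[i + 1:]:
            r_uv, p_uv, _ = pearson_with_p(values[u], values[v])
            r.loc[u, v] = r.loc[v, u] = r_uv
            p.loc[u, v] = p.loc[v, u] = p_uv
    return CorrelationMatrix(r=r, p=p, n=len(values), excluded=tuple(constant))


def build_network(corr: CorrelationMatrix, alpha: float = 0.05) -> nx.Graph:
    """Significance graph: edge (u, v) iff p_uv < alpha, carrying r and p.

    Node order follows the correlation matrix columns, so graph iteration is
    deterministic.  An empty edge set is a valid result.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    graph = nx.Graph(alpha=alpha, n=corr.n)
    graph.add_nodes_from(corr.r.columns)
    cols = list(corr.r.columns)
    for i, u in enumerate(cols):
        for v in cols[i + 1:]:
            p_uv = corr.p.loc[u, v]
            if p_uv < alpha:
                graph.add_edge(u, v, r=float(corr.r.loc[u, v]), p=float(p_uv))
    return graph


def performance_correlations(
    cohort: Cohort,
    subgroup: str = "all",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Metabolite x performance-variable Pearson correlations with p-values.

    Performance variables are the four trial times (s) and the fitted
    critical velocity (m/s).  Metabolite intensities enter on the log10
    scale, matching the normalisation used everywhere else.  ``subgroup``
    restricts to one sex ('male'/'female') or uses the full cohort ('all').
    """
    sub = cohort.subgroup(subgroup)
    if len(sub) < 3:
        raise ValueError(
            f"subgroup '{subgroup}' has {len(sub)} athletes; need >= 3"
        )
    cv_table = fit_cohort(sub).set_index("id")
    perf: dict[str, np.ndarray] = {
        f"t{d}": np.array([a.times_s[d] for a in sub.athletes]) for d in DISTANCES_M
    }
    perf["cv"] = cv_table.loc[[a.id for a in sub.athletes], "cv_mps"].to_numpy()

    panel = panel_from_cohort(sub)
    logged = np.log10(panel.data)

    rows = []
    for m in sub.metabolite_names:
        x = logged[m].to_numpy()
        for pv, y in perf.items():
            r, p, n = pearson_with_p(x, y)
            rows.append(
                {
                    "metabolite": m,
                    "performance_variable": pv,
                    "r": r,
                    "p_value": p,
                    "n": n,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


def significance_graph_from_edges(
    edges: Iterable[tuple[str, str, float, float]],
    nodes: Iterable[str] = (),
    alpha: float = 0.05,
) -> nx.Graph:
    """Build a significance graph from (u, v, r, p) tuples.

    Used by the CLI/report layer to reload exported edge lists; edges with
    p >= alpha are rejected to keep the graph's contract.
    """
    graph = nx.Graph(alpha=alpha)
    graph.add_nodes_from(nodes)
    for u, v, r, p in edges:
        if u == v:
            raise ValueError(f"self-loop on node {u!r}")
        if not p < alpha:
            raise ValueError(f"edge ({u}, {v}) has p = {p} >= alpha = {alpha}")
        graph.add_edge(u, v, r=float(r), p=float(p))
    return graph


def write_edge_list(graph: nx.Graph, path) -> None:
    """Export edges as TSV (u, v, r, p) in deterministic order."""
    rows = [
        {"u": u, "v": v, "r": d["r"], "p": d["p"]}
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["u", "v", "r", "p"]).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def read_edge_list(path, alpha: float = 0.05) -> nx.Graph:
    """Reload an exported TSV edge list into a significance graph."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in ("u", "v", "r", "p") if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    edges = [
        (str(rec.u), str(rec.v), float(rec.r), float(rec.p))
        for rec in frame.itertuples()
    ]
    return significance_graph_from_edges(edges, alpha=alpha)
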