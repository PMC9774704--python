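"""End-to-end analysis pipeline: cohort -> statistics -> network -> centrality.

A single :class:`PipelineConfig` drives every stage; the result is an
:class:`AnalysisReport` holding all stage tables plus provenance (seed,
package version, and the analysis conventions in effect), serialisable to a
deterministic JSON document and an accompanying CSV bundle / plain-text
summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import swimnet
from swimnet.cohort import (
    Cohort,
    GeneratorConfig,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from swimnet.centrality import eigenvector_centrality, weight_edges
from swimnet.network import (
    build_network,
    correlation_matrix,
    performance_correlations,
    write_edge_list,
)
from swimnet.performance import fit_cohort, summarize_group_performance
from swimnet.stats import compare_panel, log_pareto, panel_from_cohort

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline", "render_report"]

#: Analysis conventions echoed into every report's provenance block.
DECISIONS_IN_EFFECT = (
    "pooled-variance Student t with pooled-SD Cohen's d (n-1)",
    "effect sizes reported unsigned; bands small<=0.5<medium<=0.8<large",
    "distance-on-time regression; CV reported in m/s by default",
    "network correlations on the log10 scale (Pareto step is affine-invariant)",
    "no FDR on network edges (p < alpha threshold only)",
    "edge weight = 2^-(k-1) x |r|, k = 1 + min endpoint hop to target",
    "eigenvector centrality on the target's connected component only",
    "unit-Euclidean-norm scores; target excluded from the ranking",
)


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    Exactly one of ``input_csv`` and ``generator`` supplies the cohort.
    """

    input_csv: str | Path | None = None
    generator: GeneratorConfig | None = None
    alpha: float = 0.05
    target_metabolite: str = "tyrosine"
    network_subgroup: str = "all"   # all | female | male
    fdr_family: str = "joint"       # joint | per-class
    seed: int = 0
    cv_unit: str = "m/s"            # m/s | m/min (report layer conversion)

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.network_subgroup not in ("all", "female", "male"):
            raise ValueError(f"bad network_subgroup {self.network_subgroup!r}")
        if self.cv_unit not in ("m/s", "m/min"):
            raise ValueError(f"bad cv_unit {self.cv_unit!r}")
        if (self.input_csv is None) == (self.generator is None):
            raise ValueError("provide exactly one of input_csv or generator")


@dataclass
class AnalysisReport:
    """All stage outputs of one pipeline run."""

    cohort: Cohort
    performance_table: pd.DataFrame
    cv_table: pd.DataFrame
    group_stats: pd.DataFrame
    performance_correlations: dict[str, pd.DataFrame]
    network: object  # networkx.Graph
    centrality_status: str           # 'ok' | 'no edges' | 'target isolated'
    centrality: object | None        # CentralityResult or None
    provenance: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        doc = {
            "provenance": self.provenance,
            "cohort": {
                "n_male": sum(1 for a in self.cohort.athletes if a.sex == "male"),
                "n_female": sum(1 for a in self.cohort.athletes if a.sex == "female"),
                "metabolites": list(self.cohort.metabolite_names),
            },
            "performance": self.performance_table.to_dict(orient="records"),
            "cv_fits": self.cv_table.to_dict(orient="records"),
            "group_stats": self.group_stats.to_dict(orient="records"),
            "performance_correlations": {
                sex: tbl.to_dict(orient="records")
                for sex, tbl in self.performance_correlations.items()
            },
            "network": {
                "nodes": list(self.network.nodes),
                "edge_count": self.network.number_of_edges(),
                "edges": [
                    {"u": u, "v": v, "r": d["r"], "p": d["p"]}
                    for u, v, d in self.network.edges(data=True)
                ],
            },
            "centrality": {"status": self.centrality_status},
        }
        if self.centrality is not None:
            res = self.centrality
            doc["centrality"].update(
                {
                    "target": res.target,
                    "lambda": res.eigenvalue,
                    "iterations": res.iterations,
                    "converged": res.converged,
                    "scores": {n: round(s, 3) for n, s in sorted(res.scores.items())},
                    "scores_full": dict(sorted(res.scores.items())),
                    "ranking": [
                        {"node": n, "score": round(s, 3)} for n, s in res.ranking
                    ],
                }
            )
        return doc


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Run every stage; deterministic for a fixed input/config and seed."""
    if config.generator is not None:
        cohort = generate_cohort(config.generator, seed=config.seed)
        source = f"synthetic(seed={config.seed})"
    else:
        cohort = read_cohort(config.input_csv)
        source = str(config.input_csv)

    performance_table = summarize_group_performance(cohort)
    cv_table = fit_cohort(cohort)
    if config.cv_unit == "m/min":
        performance_table = performance_table.copy()
        cv_row = performance_table["variable"] == "cv"
        for col in ("mean_male", "sd_male", "mean_female", "sd_female"):
            performance_table.loc[cv_row, col] *= 60.0
        performance_table.loc[cv_row, "unit"] = "m/min"
        cv_table = cv_table.assign(cv_mps=cv_table["cv_mps"])  # table stays m/s

    panel = log_pareto(panel_from_cohort(cohort))
    group_stats = compare_panel(panel, fdr_family=config.fdr_family)

    perf_corr = {
        sex: performance_correlations(cohort, subgroup=sex, alpha=config.alpha)
        for sex in ("female", "male")
    }

    net_cohort = cohort.subgroup(config.network_subgroup)
    net_panel = log_pareto(panel_from_cohort(net_cohort))
    corr = correlation_matrix(net_panel)
    network = build_network(corr, alpha=config.alpha)

    target = config.target_metabolite
    if target not in network.nodes:
        raise ValueError(
            f"target metabolite {target!r} not among panel variables"
        )
    if network.number_of_edges() == 0:
        status, centrality = "no edges", None
    else:
        tg = weight_edges(network, target)
        component_size = sum(
            1 for h in tg.hops.values() if h != float("inf")
        )
        if component_size < 2:
            status, centrality = "target isolated", None
        else:
            status = "ok"
            centrality = eigenvector_centrality(tg)

    provenance = {
        "package": "swimnet",
        "version": swimnet.__version__,
        "seed": config.seed,
        "source": source,
        "alpha": config.alpha,
        "target_metabolite": target,
        "network_subgroup": config.network_subgroup,
        "fdr_family": config.fdr_family,
        "cv_unit": config.cv_unit,
        "decisions": list(DECISIONS_IN_EFFECT),
    }
    return AnalysisReport(
        cohort=cohort,
        performance_table=performance_table,
        cv_table=cv_table,
        group_stats=group_stats,
        performance_correlations=perf_corr,
        network=network,
        centrality_status=status,
        centrality=centrality,
        provenance=provenance,
    )


def render_report(
    report: AnalysisReport,
    outdir: str | Path,
    formats: tuple[str, ...] = ("json", "csv", "text"),
) -> dict[str, Path]:
    """Write the report: JSON always, optional CSV bundle and text summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    json_path = outdir / "report.json"
    json_path.write_text(
        json.dumps(report.to_json_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    written["json"] = json_path

    if "csv" in formats:
        write_cohort(report.cohort, outdir / "cohort.csv")
        report.performance_table.to_csv(outdir / "performance_summary.csv", index=False)
        report.cv_table.to_csv(outdir / "cv_fits.csv", index=False)
        report.group_stats.to_csv(outdir / "group_stats.csv", index=False)
        for sex, tbl in report.performance_correlations.items():
            tbl.to_csv(outdir / f"performance_correlations_{sex}.csv", index=False)
        write_edge_list(report.network, outdir / "network_edges.tsv")
        written["csv"] = outdir

    if "text" in formats:
        text_path = outdir / "summary.txt"
        text_path.write_text(_summary_text(report), encoding="utf-8")
        written["text"] = text_path
    return written


def _summary_text(report: AnalysisReport) -> str:
    lines = ["swimnet analysis summary", "=" * 24, ""]
    lines.append("Performance (mean ± SD, male vs female):")
    for rec in report.performance_table.to_dict(orient="records"):
        lines.append(
            f"  {rec['variable']:>5} [{rec['unit']}]: "
            f"male {rec['mean_male']:.1f} ± {rec['sd_male']:.1f} vs "
            f"female {rec['mean_female']:.1f} ± {rec['sd_female']:.1f}  "
            f"ES = {rec['d']:.2f} ({rec['d_class']}), p = {rec['p_value']:.3f}"
        )
    lines.append("")
    sig = report.group_stats[report.group_stats["p_value"] < report.provenance["alpha"]]
    lines.append(
        f"Metabolites at p < {report.provenance['alpha']}: "
        f"{', '.join(sig['variable']) if len(sig) else 'none'}"
    )
    lines.append(f"Network edges (p < {report.provenance['alpha']}): "
                 f"{report.network.number_of_edges()}")
    lines.append(f"Centrality stage: {report.centrality_status}")
    if report.centrality is not None:
        lines.append(
            f"Top influencers toward {report.centrality.target} "
            f"(eigenvector score, 3 dp):"
        )
        for node, score in report.centrality.ranking[:6]:
            lines.append(f"  {node}: {score:.3f}")
    lines.append("")
    return "\n".join(lines)
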