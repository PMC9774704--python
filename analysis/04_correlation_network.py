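#!/usr/bin/env python
"""Correlation analyses: metabolite--performance table and the p < 0.05 network.

Computes (i) female-subgroup Pearson correlations of each metabolite (log10
scale) with the four trial times and CV, and (ii) the all-athlete metabolite
significance network (edges where the pairwise correlation has p < 0.05).
Writes results/performance_correlations_female.csv, results/corr_r.csv,
results/corr_p.csv and results/network_edges.tsv.
"""

from pathlib import Path

from swimnet.cohort import read_cohort
from swimnet.network import (
    build_network,
    correlation_matrix,
    performance_correlations,
    write_edge_list,
)
from swimnet.stats import log_pareto, panel_from_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"
ALPHA = 0.05


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort.csv")

    female = performance_correlations(cohort, subgroup="female", alpha=ALPHA)
    female.to_csv(RESULTS / "performance_correlations_female.csv", index=False)
    tyr = female[female["metabolite"] == "tyrosine"]
    print("female tyrosine vs performance:")
    for rec in tyr.to_dict(orient="records"):
        star = " *" if rec["significant"] else ""
        print(f"  {rec['performance_variable']:>4}: r = {rec['r']:+.2f}, "
              f"p = {rec['p_value']:.3f}{star}")

    panel = log_pareto(panel_from_cohort(cohort))
    corr = correlation_matrix(panel)
    corr.r.to_csv(RESULTS / "corr_r.csv", float_format="%.6g")
    corr.p.to_csv(RESULTS / "corr_p.csv", float_format="%.6g")
    graph = build_network(corr, alpha=ALPHA)
    write_edge_list(graph, RESULTS / "network_edges.tsv")
    print(f"\nnetwork: {graph.number_of_nodes()} nodes, "
          f"{graph.number_of_edges()} edges at p < {ALPHA}")
    print(f"wrote {RESULTS / 'network_edges.tsv'}")


if __name__ == "__main__":
    main()
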