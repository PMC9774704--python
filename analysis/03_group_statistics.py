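#!/usr/bin/env python
"""Group statistics: performance effect sizes and the metabolite panel t-tests.

Performance variables (trial times and CV) are compared male vs female with
pooled-SD Cohen's d.  The metabolite panel is log10 + Pareto normalised,
then tested per variable with the pooled t-test and BH-FDR over the joint
32-metabolite family.  Writes results/performance_summary.csv and
results/group_stats.csv.
"""

from pathlib import Path

from swimnet.cohort import read_cohort
from swimnet.performance import summarize_group_performance
from swimnet.stats import compare_panel, log_pareto, panel_from_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort.csv")

    perf = summarize_group_performance(cohort)
    perf.to_csv(RESULTS / "performance_summary.csv", index=False)
    print("performance (male vs female):")
    for rec in perf.to_dict(orient="records"):
        print(
            f"  {rec['variable']:>5}: male {rec['mean_male']:.2f} ± {rec['sd_male']:.2f} "
            f"vs female {rec['mean_female']:.2f} ± {rec['sd_female']:.2f} "
            f"[{rec['unit']}]  ES = {rec['d']:.2f} ({rec['d_class']}), p = {rec['p_value']:.3f}"
        )

    panel = log_pareto(panel_from_cohort(cohort))
    stats = compare_panel(panel, fdr_family="joint")
    stats.to_csv(RESULTS / "group_stats.csv", index=False)
    sig = stats[stats["q_value"] < 0.05]
    print("\nmetabolites at q < 0.05 (joint BH family):")
    if len(sig) == 0:
        print("  none")
    for rec in sig.to_dict(orient="records"):
        print(
            f"  {rec['variable']}: d = {rec['d']:.2f} ({rec['d_class']}), "
            f"p = {rec['p_value']:.4f}, q = {rec['q_value']:.4f}"
        )
    print(f"\nwrote {RESULTS / 'performance_summary.csv'} and {RESULTS / 'group_stats.csv'}")


if __name__ == "__main__":
    main()
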