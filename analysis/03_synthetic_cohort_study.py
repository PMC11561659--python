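"""Full synthetic study: simulate 72 subjects, fit, and run the statistics.

Emits the study tables under results/: demographics summary
(table1_demographics.csv), metric-age and metric-volume partial
correlations with FDR (table2_age_correlations.csv /
table2_volume_correlations.csv), ANCOVA group comparisons
(group_comparisons.csv), linear/quadratic age trends (age_trends.csv),
and the planted-vs-recovered report (recovery_report.csv).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from sandimri.cohort import SyntheticCohortConfig, run_end_to_end

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7


def main():
    res = run_end_to_end(SyntheticCohortConfig(seed=SEED))

    subj = res["subjects"]
    demo = subj.groupby("group").agg(
        n=("subject", "size"),
        n_female=("sex", lambda s: int((s == "F").sum())),
        age_mean=("age", "mean"), age_sd=("age", "std"),
        age_min=("age", "min"), age_max=("age", "max")).round(1)
    demo.loc["total"] = [len(subj), int((subj.sex == "F").sum()),
                         round(subj.age.mean(), 1), round(subj.age.std(), 1),
                         subj.age.min().round(1), subj.age.max().round(1)]
    demo.to_csv(OUT / "table1_demographics.csv")
    print("Demographics:")
    print(demo.to_string(), "\n")

    res["age_correlations"].round(4).to_csv(
        OUT / "table2_age_correlations.csv", index=False)
    res["volume_correlations"].round(4).to_csv(
        OUT / "table2_volume_correlations.csv", index=False)
    res["cohort"].round(5).to_csv(OUT / "cohort.csv", index=False)
    res["ground_truth"].round(5).to_csv(OUT / "ground_truth.csv", index=False)

    rows = []
    for region, per_metric in res["ancova"].items():
        for metric, g in per_metric.items():
            rows.append({"region": region, "metric": metric,
                         "F": g.f_stat, "p": g.p})
    pd.DataFrame(rows).round(4).to_csv(OUT / "group_comparisons.csv",
                                       index=False)

    rows = []
    for region, per_metric in res["age_trends"].items():
        for metric, t in per_metric.items():
            rows.append({"region": region, "metric": metric,
                         "r2_linear": t.r2_linear,
                         "r2_quadratic": t.r2_quadratic,
                         "peak_age": t.peak_age})
    pd.DataFrame(rows).round(4).to_csv(OUT / "age_trends.csv", index=False)

    rec = res["recovery"].round(3)
    rec.to_csv(OUT / "recovery_report.csv", index=False)
    print("Planted vs recovered age correlations:")
    print(rec.to_string(index=False))
    ctx = rec[rec.region == "cortex"].set_index("metric")
    print(f"\nThe declining soma fraction is recovered in direction "
          f"(recovered r = {ctx.loc['f_is', 'recovered_r']:.2f} vs planted "
          f"{ctx.loc['f_is', 'planted_r']:.2f}) but attenuated by forest "
          "estimation error — see docs/methods.md on the soma/ball "
          "degeneracy at these pulse timings.")


if __name__ == "__main__":
    main()
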