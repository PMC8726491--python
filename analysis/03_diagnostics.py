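#!/usr/bin/env python
"""Diagnostic-accuracy and correlation tables from the cohort measurements.

Reads results/cohort.csv and results/measurements.csv (produced by
02_measure_cohort.py), and writes machine twins of the study's report tables:

* table_roc.csv          -- per index: AUC with 95% CI, Youden cutoff,
                            sensitivity, specificity, PPV, NPV
* table_correlations.csv -- per index: Spearman rho vs T-score and vs BMD
* table_boxplot.csv      -- per index and group: five-number summary
* table_delong.csv       -- 2D-vs-3D correlated-AUC comparisons
"""

from pathlib import Path

import pandas as pd

from femhu import RunConfig
from femhu.pipeline import build_report

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = pd.read_csv(RESULTS / "cohort.csv")
    measurements = pd.read_csv(RESULTS / "measurements.csv")
    report = build_report(RunConfig(), cohort, measurements)

    roc_rows = []
    for key, r in report.roc.items():
        roc_rows.append(dict(
            index=key, auc=round(r.auc, 3), ci_low=round(r.ci95[0], 3),
            ci_high=round(r.ci95[1], 3), direction=r.direction,
            cutoff=round(r.cutoff, 1), sens=round(r.sens, 1),
            spec=round(r.spec, 1), ppv=round(r.ppv, 1), npv=round(r.npv, 1),
        ))
    pd.DataFrame(roc_rows).to_csv(RESULTS / "table_roc.csv", index=False)

    corr_rows = []
    for key, c in report.corr.items():
        corr_rows.append(dict(
            index=key,
            rho_t_score=round(c["vs_t_score"].rho, 2),
            t_category=c["vs_t_score"].category,
            rho_bmd=round(c["vs_bmd"].rho, 2),
            bmd_category=c["vs_bmd"].category,
        ))
    pd.DataFrame(corr_rows).to_csv(RESULTS / "table_correlations.csv", index=False)

    box_rows = []
    for key, five in report.boxplot.items():
        if key.endswith("-non-osteoporosis"):
            idx, group = key[: -len("-non-osteoporosis")], "non-osteoporosis"
        else:
            idx, group = key[: -len("-osteoporosis")], "osteoporosis"
        box_rows.append(dict(index=idx, group=group, minimum=five[0], q1=five[1],
                             median=five[2], q3=five[3], maximum=five[4]))
    pd.DataFrame(box_rows).to_csv(RESULTS / "table_boxplot.csv", index=False)

    delong_rows = [
        dict(index=k, auc_2d=round(d.auc_a, 3), auc_3d=round(d.auc_b, 3),
             z=round(d.z, 2), p=round(d.p_value, 3))
        for k, d in report.delong_2d_vs_3d.items()
    ]
    pd.DataFrame(delong_rows).to_csv(RESULTS / "table_delong.csv", index=False)

    best = max(report.roc.items(), key=lambda kv: kv[1].auc)
    print("ROC summary (AUC / cutoff / sens / spec):")
    for row in roc_rows:
        print(f"  {row['index']:22s} {row['auc']:.3f}  {row['cutoff']:7.1f}  "
              f"{row['sens']:5.1f}%  {row['spec']:5.1f}%")
    print(f"best index: {best[0]} (AUC {best[1].auc:.3f})")
    print("2D-vs-3D DeLong p-values:",
          {k: row['p'] for k, row in zip(report.delong_2d_vs_3d, delong_rows)})
    print(f"wrote tables to {RESULTS}")


if __name__ == "__main__":
    main()
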