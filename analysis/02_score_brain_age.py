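#!/usr/bin/env python
"""Score the cohort: normative adjustment, ROI weights, bounded brain age.

Reads results/cohort.csv and results/reference.csv (run 01 first), fits the
per-(ROI, sex) normative model on the reference, derives CU/CI weights,
scores every subject and reports the older/younger x converter table with
its odds ratio.  Writes brainage_results.csv, normative_model.json,
roi_weights.csv and a brain-vs-chronological-age scatter.

    python analysis/02_score_brain_age.py --out results
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from brainagemci.brainage import classify_cohort, compute_weights, results_frame, score_cohort
from brainagemci.cohort_io import DEFAULT_ROIS, RoiVolumeTable, read_cohort
from brainagemci.normative import adjust_table, fit_normative
from brainagemci.stats import ContingencyTable2x2, odds_ratio_ci


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    records, volumes, errors = read_cohort(args.out / "cohort.csv")
    assert not errors
    ref = pd.read_csv(args.out / "reference.csv", index_col="subject_id")
    reference = RoiVolumeTable(ref[[r.name for r in DEFAULT_ROIS]], DEFAULT_ROIS)

    model = fit_normative(reference, ref["age"], ref["sex"])
    model.to_json(args.out / "normative_model.json")

    cu_z, _ = adjust_table(reference, ref["age"], ref["sex"], model)
    ages = pd.Series({r.subject_id: r.age_scan for r in records})
    sexes = pd.Series({r.subject_id: r.sex for r in records})
    ci_z, _ = adjust_table(volumes, ages, sexes, model)
    weights = compute_weights(cu_z, ci_z)
    pd.DataFrame(
        {"weight": weights.weights, "sign": weights.signs}
    ).rename_axis("roi").to_csv(args.out / "roi_weights.csv")

    results = score_cohort(records, volumes, model, weights)
    frame = results_frame(results)
    frame.to_csv(args.out / "brainage_results.csv")

    cls = classify_cohort(results, {r.subject_id: r.converted for r in records})
    a, b, c, d = cls.counts_2x2()
    orr = odds_ratio_ci(ContingencyTable2x2(a, b, c, d))
    print("four-group sizes (1=younger/nc 2=older/nc 3=younger/c 4=older/c):",
          cls.group_sizes)
    print(f"older conversion rate  {100 * a / (a + b):.1f}% ({a}/{a + b})")
    print(f"younger conversion rate {100 * c / (c + d):.1f}% ({c}/{c + d})")
    print(f"odds ratio {orr.odds_ratio:.2f} "
          f"(95% CI {orr.ci_lower:.2f}-{orr.ci_upper:.2f})")

    fig, ax = plt.subplots(figsize=(5, 5))
    conv = frame.index.map({r.subject_id: r.converted for r in records})
    for is_conv, color, label in ((False, "gray", "non-converter"),
                                  (True, "purple", "converter")):
        sub = frame[conv == is_conv]
        ax.scatter(sub["age_scan"], sub["brain_age"], s=18, c=color, label=label)
    lims = [frame["age_scan"].min() - 2, frame["age_scan"].max() + 2]
    ax.plot(lims, lims, "r-", lw=1)
    ax.set_xlabel("chronological age at scan (years)")
    ax.set_ylabel("brain age (years)")
    ax.legend()
    (args.out / "figures").mkdir(exist_ok=True)
    fig.savefig(args.out / "figures" / "brain_vs_chronological_age.png", dpi=120)
    print(f"wrote brainage_results.csv and figures under {args.out}/")


if __name__ == "__main__":
    main()
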