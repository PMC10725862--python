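#!/usr/bin/env python
"""Baseline comparisons and neuropsych x volume correlation matrices.

Reads the simulated cohort and the brain-age results (run 01 and 02 first),
compares converters vs non-converters on the baseline table (screened test
selection), compares subgroups 1/2/4 with BH-adjusted Kruskal-Wallis, and
writes Spearman rho/p matrices per conversion group.

    python analysis/03_group_comparisons.py --out results
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from brainagemci.cohort_io import NEUROPSYCH_TESTS, read_cohort, records_frame
from brainagemci.pipeline import SUBGROUP_VARIABLES, TABLE1_VARIABLES
from brainagemci.stats import compare_groups, spearman_matrix


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    records, volumes, _ = read_cohort(args.out / "cohort.csv")
    ba = pd.read_csv(args.out / "brainage_results.csv", index_col="subject_id")
    df = records_frame(records)
    df["sex"] = (df["sex"] == "female").astype(float)
    df["apoe4_carrier"] = df["apoe4_carrier"].astype(float)
    df["conversion_group"] = np.where(df["converted"], "converter", "non_converter")

    rows = []
    table1 = compare_groups(
        df, "conversion_group", [v for v, _ in TABLE1_VARIABLES],
        kinds=dict(TABLE1_VARIABLES),
    )
    for r in table1:
        rows.append({"variable": r.variable, "method": r.method,
                     "statistic": r.statistic, "p": r.p_value, **r.group_summaries})
    pd.DataFrame(rows).to_csv(args.out / "table1_comparisons.csv", index=False)
    print("baseline comparisons (converter vs non-converter):")
    for r in table1:
        flag = "*" if r.p_value < 0.05 else ""
        print(f"  {r.variable:16s} {r.method:15s} p={r.p_value:.3f}{flag}")

    # subgroups 1 (younger/nc), 2 (older/nc), 4 (older/c); group 3 too small
    older = ba["direction"] == "older"
    group = np.where(df["converted"], np.where(older.reindex(df.index), 4, 3),
                     np.where(older.reindex(df.index), 2, 1))
    df["group"] = group.astype(str)
    sub = df[df["group"].isin(["1", "2", "4"])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = compare_groups(sub, "group", list(SUBGROUP_VARIABLES), adjust=True)
    rows = [{"variable": r.variable, "method": r.method, "p": r.p_value,
             "bh_adjusted_p": r.adjusted_p, **r.group_summaries} for r in res]
    pd.DataFrame(rows).to_csv(args.out / "subgroup_comparisons.csv", index=False)
    sig = [r.variable for r in res if r.adjusted_p < 0.05]
    print(f"subgroup (1 vs 2 vs 4) BH-significant variables: {sig or 'none'}")

    score_cols = ["kmmse", "cdr_sob", "gds_stage", "education_years"] + list(
        NEUROPSYCH_TESTS
    )
    for label, mask in (("converter", df["converted"].astype(bool)),
                        ("non_converter", ~df["converted"].astype(bool))):
        ids = df.index[mask]
        rho, p = spearman_matrix(df.loc[ids, score_cols].astype(float),
                                 volumes.volumes.loc[ids])
        rho.to_csv(args.out / f"spearman_rho_{label}.csv")
        p.to_csv(args.out / f"spearman_p_{label}.csv")
        strong = int((rho.abs() > 0.3).sum().sum())
        print(f"{label}: {strong} score-ROI pairs with |rho| > 0.3")


if __name__ == "__main__":
    main()
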