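#!/usr/bin/env python
"""Kaplan-Meier / log-rank / Cox analysis of dementia conversion.

Reads the cohort and brain-age results (run 01 and 02 first) and compares
conversion-free survival between older and younger by brain age, across the
four sex x education strata, and across the eight sex x education x
brain-age strata.  Writes per-stratum KM curves, the log-rank tests, a
generic Cox fit and the stratified KM figure.

    python analysis/04_survival_analysis.py --out results
"""

import argparse
import json
import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from brainagemci.brainage import ScoringConfig, compute_brain_age
from brainagemci.cohort_io import read_cohort
from brainagemci.survival import (
    cox_fit,
    curve_frame,
    logrank_test,
    stratified_analysis,
    survival_input_from_records,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    records, _, _ = read_cohort(args.out / "cohort.csv")
    ba = pd.read_csv(args.out / "brainage_results.csv", index_col="subject_id")
    # rebuild minimal per-subject results carrying the scored direction
    cfg = ScoringConfig()
    results = [
        compute_brain_age(
            sid, row["age_scan"], row["gap"], {"any": row["gap"] > 0},
            {"any": abs(row["gap"])}, cfg,
        )
        for sid, row in ba.iterrows()
    ]

    tests = {}
    direction = {r.subject_id: r.direction for r in results}
    stat, dof, p = logrank_test(survival_input_from_records(records, direction))
    tests["older_vs_younger"] = {"statistic": stat, "df": dof, "p": p}
    print(f"older vs younger log-rank: chi2={stat:.2f}, p={p:.4f}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        strat = stratified_analysis(records, results)
    for key, res in strat.items():
        tests[key] = {"statistic": res.statistic, "df": res.df, "p": res.p_value,
                      "sizes": res.sizes}
        print(f"{key} log-rank: chi2={res.statistic:.2f}, df={res.df}, "
              f"p={res.p_value:.4f}")
        for name, curve in res.curves.items():
            curve_frame(curve).to_csv(args.out / f"km_{key}_{name}.csv", index=False)

    cov = pd.DataFrame(
        {
            "older_by_brain_age": [float(direction[r.subject_id] == "older") for r in records],
            "male": [float(r.sex == "male") for r in records],
            "education_years": [r.education_years for r in records],
        },
        index=[r.subject_id for r in records],
    )
    cox = cox_fit(survival_input_from_records(records), cov)
    cox.to_csv(args.out / "cox_fit.csv")
    hr = cox.loc["older_by_brain_age"]
    print(f"Cox HR (older by brain age): {hr['hr']:.2f} "
          f"(95% CI {hr['ci_lower']:.2f}-{hr['ci_upper']:.2f}, p={hr['p']:.4f})")
    (args.out / "survival_tests.json").write_text(
        json.dumps(tests, indent=1), encoding="utf-8"
    )

    fig, ax = plt.subplots(figsize=(7, 5))
    for name, curve in sorted(strat["eight_group"].curves.items()):
        t = [0.0] + list(curve.times) + [36.0]
        s = [1.0] + list(curve.survival) + [curve.at(36.0)]
        ax.step(t, s, where="post", label=f"{name} (n={strat['eight_group'].sizes[name]})")
    ax.set_xlabel("months since baseline")
    ax.set_ylabel("conversion-free probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=7)
    (args.out / "figures").mkdir(exist_ok=True)
    fig.savefig(args.out / "figures" / "km_eight_group.png", dpi=120)
    print(f"wrote KM curves, cox_fit.csv, survival_tests.json under {args.out}/")


if __name__ == "__main__":
    main()
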