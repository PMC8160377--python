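"""Dose-volume metrics and constraint verdicts for all plans.

Evaluates D98%/D50%/D2% for the boost volume, ground-truth tumour, urethra
and PRV-urethra on every case and plan, with and without intrafractional
motion blurring, and checks the protocol dose constraints.  Mirrors the
layout of a dosimetric comparison table: one row per (case, plan, motion,
structure).

Writes results/dose_metrics.csv and results/constraints.csv.

Run:  python analysis/02_dose_metrics.py [--seed 1]
"""

import argparse
from pathlib import Path

import pandas as pd

from planrbe import (
    BOOST_ROLE,
    MotionKernel,
    Role,
    blur_dose,
    boost_constraints,
    check_constraints,
    DEFAULT_CONSTRAINTS,
    dose_at_volume,
    make_cohort,
)
from planrbe.grid import PlanCase


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-cases", type=int, default=10)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = make_cohort(args.n_cases, seed=args.seed)
    kernel = MotionKernel()
    metric_rows, verdict_rows = [], []
    for case in cohort:
        for motion in (False, True):
            dose = blur_dose(case.dose, kernel) if motion else case.dose
            eval_case = PlanCase(case.case_id, case.plan_label, dose, case.structures)
            boost_role = BOOST_ROLE[case.plan_label]
            for role in (boost_role, Role.GTV_HISTO, Role.URETHRA, Role.PRV_URETHRA):
                mask = case.structures.by_role(role)
                row = {
                    "case_id": case.case_id,
                    "plan": case.plan_label,
                    "motion": motion,
                    "structure": "boost" if role == boost_role else role.value.lower(),
                }
                for pct in (98, 50, 2):
                    row[f"d{pct}pct_gy"] = dose_at_volume(dose, mask, pct)
                metric_rows.append(row)
            table = check_constraints(
                eval_case, list(DEFAULT_CONSTRAINTS) + boost_constraints(boost_role)
            )
            table.insert(0, "case_id", case.case_id)
            table.insert(1, "plan", case.plan_label)
            table.insert(2, "motion", motion)
            verdict_rows.append(table)

    metrics = pd.DataFrame(metric_rows)
    verdicts = pd.concat(verdict_rows, ignore_index=True)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    metrics.to_csv(args.out_dir / "dose_metrics.csv", index=False)
    verdicts.to_csv(args.out_dir / "constraints.csv", index=False)

    med = metrics.groupby(["structure", "plan", "motion"]).median(numeric_only=True)
    print("median D98/D50/D2 (Gy) per structure, plan and motion state:")
    print(med.round(2).to_string())
    urethral = verdicts[verdicts.structure.isin(["URETHRA", "PRV_URETHRA"])]
    fail = urethral[urethral.status == "fail"]
    print("\nurethral D2% <= 62.4 Gy failures per plan/motion (cases out of "
          f"{args.n_cases}):")
    if fail.empty:
        print("  none")
    else:
        print(fail.groupby(["plan", "motion", "structure"]).size().to_string())


if __name__ == "__main__":
    main()
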