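"""Cohort evaluation, summaries and paired exact statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .composite import p_plus, probability_of_injury
from .grid import BOOST_ROLE, PlanCase, Role
from .metrics import Constraint, DEFAULT_CONSTRAINTS, check_constraints, dose_at_volume
from .models import ntcp_lkb, ntcp_relative_seriality, tcp_poisson, voxel_eqd
from .motion import MotionKernel, blur_dose
from .params import RadiobioParams

#: structures reported with D98%/D50%/D2% in the dosimetric table
_DVH_ROLES = (Role.GTV_HISTO, Role.URETHRA, Role.PRV_URETHRA)


@dataclass
class OutcomeRecord:
    """Per-case, per-plan radiobiological outcome (one motion state)."""

    case_id: str
    plan_label: str
    motion: bool
    tcp: float
    ntcp_urethra: float
    ntcp_bladder: float
    ntcp_rectum: float
    p_injury: float
    p_plus: float
    dvh_metrics: dict[str, float] = field(default_factory=dict)
    constraints: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for name in ("tcp", "ntcp_urethra", "ntcp_bladder", "ntcp_rectum",
                     "p_injury", "p_plus"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.p_plus > self.tcp + 1e-12:
            raise ValueError("P+ cannot exceed TCP")

    def to_dict(self) -> dict:
        out = {
            "case_id": self.case_id,
            "plan": self.plan_label,
            "motion": self.motion,
            "tcp": self.tcp,
            "ntcp_urethra": self.ntcp_urethra,
            "ntcp_bladder": self.ntcp_bladder,
            "ntcp_rectum": self.ntcp_rectum,
            "p_injury": self.p_injury,
            "p_plus": self.p_plus,
        }
        out.update(self.dvh_metrics)
        return out


def _evaluate_one(
    case: PlanCase,
    dose,
    params: RadiobioParams,
    motion: bool,
    constraints: Sequence[Constraint],
) -> OutcomeRecord:
    s = case.structures
    required = [Role.GTV_HISTO, Role.URETHRA, Role.BLADDER, Role.RECTUM]
    missing = [r.value for r in required if not s.has_role(r)]
    if missing:
        raise ValueError(f"case {case.case_id} is missing structures: {missing}")

    eqd0 = voxel_eqd(dose, params.tumour.ab_ratio, reference_fraction_size=0.0)
    tcp = tcp_poisson(eqd0, s.by_role(Role.GTV_HISTO), params.tumour)
    ntcps = {
        "urethra": ntcp_lkb(dose, s.by_role(Role.URETHRA), params.urethra),
        "bladder": ntcp_relative_seriality(dose, s.by_role(Role.BLADDER), params.bladder),
        "rectum": ntcp_relative_seriality(dose, s.by_role(Role.RECTUM), params.rectum),
    }
    p_i = probability_of_injury(ntcps, params.weights)

    dvh: dict[str, float] = {}
    report_roles = list(_DVH_ROLES) + [BOOST_ROLE[case.plan_label]]
    for role in report_roles:
        if not s.has_role(role):
            continue
        mask = s.by_role(role)
        key = "boost" if role == BOOST_ROLE[case.plan_label] else role.value.lower()
        for pct in (98, 50, 2):
            dvh[f"{key}_d{pct}pct"] = dose_at_volume(dose, mask, pct)

    shadow = PlanCase(case.case_id, case.plan_label, dose, s)
    verdicts = check_constraints(shadow, constraints)
    return OutcomeRecord(
        case.case_id,
        case.plan_label,
        motion,
        tcp,
        ntcps["urethra"],
        ntcps["bladder"],
        ntcps["rectum"],
        p_i,
        p_plus(tcp, p_i),
        dvh,
        verdicts,
    )


def evaluate_case(
    case: PlanCase,
    params: RadiobioParams | None = None,
    kernel: MotionKernel | None = None,
    constraints: Sequence[Constraint] = DEFAULT_CONSTRAINTS,
) -> list[OutcomeRecord]:
    """Evaluate one plan case: TCP, NTCPs, P_I, P+, DVH metrics, verdicts.

    Returns one record without motion and, when a kernel is given, a second
    record on the motion-blurred dose against the same (fixed) structures.
    """
    params = params or RadiobioParams()
    records = [_evaluate_one(case, case.dose, params, False, constraints)]
    if kernel is not None:
        blurred = blur_dose(case.dose, kernel)
        records.append(_evaluate_one(case, blurred, params, True, constraints))
    return records


def evaluate_cohort(
    cohort: Iterable[PlanCase],
    params: RadiobioParams | None = None,
    kernel: MotionKernel | None = None,
    constraints: Sequence[Constraint] = DEFAULT_CONSTRAINTS,
) -> list[OutcomeRecord]:
    records: list[OutcomeRecord] = []
    for case in cohort:
        records.extend(evaluate_case(case, params, kernel, constraints))
    return records


def records_frame(records: Iterable[OutcomeRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records])


def summarize_cohort(records: Iterable[OutcomeRecord]) -> pd.DataFrame:
    """Median and IQR of every endpoint per (plan, motion) group.

    Median uses the midpoint convention for even counts (numpy default).
    """
    df = records_frame(records)
    if df.empty:
        raise ValueError("no records to summarize")
    value_cols = [c for c in df.columns if c not in ("case_id", "plan", "motion")]
    rows = []
    for (plan, motion), grp in df.groupby(["plan", "motion"]):
        for col in value_cols:
            v = grp[col].to_numpy(dtype=float)
            rows.append(
                {
                    "plan": plan,
                    "motion": motion,
                    "endpoint": col,
                    "median": float(np.median(v)),
                    "iqr_low": float(np.percentile(v, 25)),
                    "iqr_high": float(np.percentile(v, 75)),
                    "n": len(v),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank


def wilcoxon_signed_rank_exact(
    x: Sequence[float],
    y: Sequence[float],
    zero_method: str = "wilcox",
) -> float:
    """Two-sided exact Wilcoxon matched-pairs signed-rank p-value.

    The exact null distribution of the positive-rank sum over all 2^m sign
    assignments of the m nonzero differences is built by the subset-sum
    recursion (equivalent to full enumeration); tied absolute differences
    receive midranks.  ``zero_method`` "wilcox" drops zero differences, the
    "pratt" variant keeps them in the ranking and then discards their
    contribution.  p = min(1, 2 * min(lower tail, upper tail)); all-zero
    differences give p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D sequences")
    d = x - y
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    if np.all(d == 0):
        warnings.warn("all differences are zero; p = 1", stacklevel=2)
        return 1.0
    if zero_method == "wilcox":
        d = d[d != 0]
        absd = np.abs(d)
        ranks = _midranks(absd)
    else:  # pratt: rank zeros too, then drop them
        absd = np.abs(d)
        ranks_all = _midranks(absd)
        keep = d != 0
        d, ranks = d[keep], ranks_all[keep]
    m = d.size
    if m > 25:
        raise ValueError("exact mode supports at most 25 nonzero differences")
    # doubled midranks are integers -> subset-sum distribution
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: counts.size - r]
    counts /= 2.0**m
    w2 = int(np.round(2 * ranks[d > 0].sum()))
    lower = counts[: w2 + 1].sum()
    upper = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size, dtype=float)
    sorted_v = values[order]
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


_ENDPOINTS = ("p_plus", "tcp", "ntcp_urethra", "ntcp_bladder", "ntcp_rectum")
_PLAN_PAIRS = (("plan1", "plan2"), ("plan1", "plan3"), ("plan2", "plan3"))


def compare_plans(
    records: Iterable[OutcomeRecord],
    endpoints: Sequence[str] = _ENDPOINTS,
    zero_method: str = "wilcox",
) -> pd.DataFrame:
    """Pairwise plan comparison per endpoint and motion state.

    Records are matched by case id within each motion state; for every plan
    pair the exact Wilcoxon p and the sign of the median paired difference
    are reported.  Unmatched cases raise.
    """
    df = records_frame(records)
    rows = []
    for motion, grp in df.groupby("motion"):
        wide = grp.pivot(index="case_id", columns="plan")
        for endpoint in endpoints:
            for a, b in _PLAN_PAIRS:
                if (endpoint, a) not in wide.columns or (endpoint, b) not in wide.columns:
                    continue
                xa = wide[(endpoint, a)]
                xb = wide[(endpoint, b)]
                if xa.isna().any() or xb.isna().any():
                    raise ValueError(f"unmatched cases for {endpoint} {a} vs {b}")
                p = wilcoxon_signed_rank_exact(xa.to_numpy(), xb.to_numpy(), zero_method)
                med_diff = float(np.median(xb.to_numpy() - xa.to_numpy()))
                rows.append(
                    {
                        "motion": motion,
                        "endpoint": endpoint,
                        "pair": f"{a}_vs_{b}",
                        "p_value": p,
                        "median_diff": med_diff,
                        "direction": "higher" if med_diff > 0 else
                                     ("lower" if med_diff < 0 else "equal"),
                    }
                )
    return pd.DataFrame(rows)
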