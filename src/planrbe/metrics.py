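"""DVH metrics, dose constraints, and structure-geometry metrics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import DoseGrid, PlanCase, Role, StructureMask


def dose_at_volume(dose: DoseGrid, mask: StructureMask, percent: float) -> float:
    """DX%: the largest dose level received by at least X% of the structure.

    Exact order statistics over the structure's voxel doses (no binning):
    with the doses sorted descending, DX% is the ceil(X/100 * n)-th value.
    D0% is the maximum, D100% the minimum.
    """
    if mask.is_empty():
        raise ValueError(f"mask {mask.name!r} is empty")
    if not 0 <= percent <= 100:
        raise ValueError("percent must be in [0, 100]")
    d = np.sort(dose.values[mask.occupancy])[::-1]
    k = int(np.ceil(percent / 100.0 * d.size))
    if k == 0:
        return float(d[0])
    return float(d[k - 1])


def cumulative_dvh(
    dose: DoseGrid, mask: StructureMask, bin_width: float = 0.1
) -> pd.DataFrame:
    """Cumulative DVH: % of structure volume receiving >= each dose level.

    Levels run from 0 to just above the structure maximum in ``bin_width``
    steps; the curve is monotone non-increasing from 100%.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if mask.is_empty():
        raise ValueError(f"mask {mask.name!r} is empty")
    d = dose.values[mask.occupancy]
    levels = np.arange(0.0, d.max() + 2 * bin_width, bin_width)
    frac = [(d >= lv).mean() * 100.0 for lv in levels]
    return pd.DataFrame({"dose_gy": levels, "volume_pct": frac})


@dataclass(frozen=True)
class Constraint:
    """One dose-volume constraint, e.g. urethra D2% <= 62.4 Gy."""

    role: Role
    metric: str  # "D2%" or "V60Gy"
    bound: Literal["<=", ">="]
    threshold: float  # Gy for DX%, % volume for VX Gy

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if not (self.metric.startswith("D") or self.metric.startswith("V")):
            raise ValueError(f"unknown metric {self.metric!r}")


#: urethral and whole-prostate-target constraints of the 60/70 Gy in 20 fx
#: protocol.  The PTV2 near-maximum limit is omitted because the boost
#: volume lies inside PTV2, which makes that limit apply only outside the
#: boost; the urethra/PRV D2% limit of 62.4 Gy is the sparing driver.
DEFAULT_CONSTRAINTS: list[Constraint] = [
    Constraint(Role.PTV2, "D98%", ">=", 58.8),
    Constraint(Role.URETHRA, "D2%", "<=", 62.4),
    Constraint(Role.PRV_URETHRA, "D2%", "<=", 62.4),
]

#: boost-volume coverage/near-maximum constraints; the boost role differs
#: per plan, so these are built on demand
def boost_constraints(boost_role: Role) -> list[Constraint]:
    return [
        Constraint(boost_role, "D98%", ">=", 68.6),
        Constraint(boost_role, "D2%", "<=", 71.4),
    ]


def _measure(dose: DoseGrid, mask: StructureMask, metric: str) -> float:
    if metric.startswith("D") and metric.endswith("%"):
        return dose_at_volume(dose, mask, float(metric[1:-1]))
    if metric.startswith("V") and metric.endswith("Gy"):
        level = float(metric[1:-2])
        return float((dose.values[mask.occupancy] >= level).mean() * 100.0)
    raise ValueError(f"unknown metric {metric!r}")


def check_constraints(
    case: PlanCase, constraints: Sequence[Constraint] = DEFAULT_CONSTRAINTS
) -> pd.DataFrame:
    """Evaluate each constraint; one row per constraint.

    Columns: structure, metric, bound, threshold, measured, status, where
    status is "pass"/"fail"/"not-evaluable" (missing structures are never
    reported as a pass).
    """
    rows = []
    for c in constraints:
        try:
            mask = case.structures.by_role(c.role)
        except KeyError:
            rows.append((c.role.value, c.metric, c.bound, c.threshold, np.nan, "not-evaluable"))
            continue
        value = _measure(case.dose, mask, c.metric)
        ok = value <= c.threshold if c.bound == "<=" else value >= c.threshold
        rows.append(
            (c.role.value, c.metric, c.bound, c.threshold, value, "pass" if ok else "fail")
        )
    return pd.DataFrame(
        rows, columns=["structure", "metric", "bound", "threshold", "measured", "status"]
    )


def overlap_metrics(a: StructureMask, b: StructureMask) -> dict[str, float]:
    """Sorensen-Dice overlap and directed coverage between two masks.

    Returns dice = 2|A∩B|/(|A|+|B|), the intersection volume in cm^3,
    the intersection as % of |B|, and the coverage of A by B in %
    (|A∩B|/|A| * 100).
    """
    if not a.geometry.same_as(b.geometry):
        raise ValueError("masks have different geometries")
    na, nb = a.voxel_count, b.voxel_count
    inter = int((a.occupancy & b.occupancy).sum())
    if na + nb == 0:
        warnings.warn("both masks empty; dice defined as 0", stacklevel=2)
        dice = 0.0
    else:
        dice = 2.0 * inter / (na + nb)
    return {
        "dice": dice,
        "intersection_cm3": inter * a.geometry.voxel_volume_cm3,
        "intersection_pct_of_b": 100.0 * inter / nb if nb else 0.0,
        "coverage_of_a_by_b_pct": 100.0 * inter / na if na else 0.0,
    }


def _min_distance_3d(a_occ: np.ndarray, b_occ: np.ndarray, spacing) -> float:
    if (a_occ & b_occ).any():
        return 0.0
    # exact: Euclidean distance transform of B's complement gives, at every
    # voxel centre, the distance to the nearest B voxel centre
    dist_to_b = ndimage.distance_transform_edt(~b_occ, sampling=spacing)
    return float(dist_to_b[a_occ].min())


def min_distance(
    a: StructureMask,
    b: StructureMask,
    mode: Literal["3d", "per_axial_slice"] = "3d",
) -> float | tuple[dict[int, float], float]:
    """Minimum Euclidean distance between voxel centres of two masks, mm.

    Anisotropic spacing is respected; overlapping masks give 0.  In
    ``per_axial_slice`` mode both masks are restricted to each CC slice
    where both are present; returns ({slice index: distance}, overall
    minimum of the per-slice values).
    """
    if a.is_empty() or b.is_empty():
        raise ValueError("min_distance requires two non-empty masks")
    if not a.geometry.same_as(b.geometry):
        raise ValueError("masks have different geometries")
    sp = a.geometry.spacing
    if mode == "3d":
        return _min_distance_3d(a.occupancy, b.occupancy, sp)
    if mode != "per_axial_slice":
        raise ValueError(f"unknown mode {mode!r}")
    per_slice: dict[int, float] = {}
    for iz in range(a.geometry.dims[2]):
        sa = a.occupancy[:, :, iz]
        sb = b.occupancy[:, :, iz]
        if sa.any() and sb.any():
            per_slice[iz] = _min_distance_3d(sa, sb, sp[:2])
    if not per_slice:
        raise ValueError("no axial slice contains both masks")
    return per_slice, min(per_slice.values())
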