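"""Composite outcome statistics: P_I, P+ and parameter-uncertainty scans."""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import DoseGrid, PlanCase, Role, StructureMask
from .models import LKBParams, LQParams, ntcp_lkb, tcp_poisson, voxel_eqd


def probability_of_injury(
    ntcps: Mapping[str, float] | Sequence[float],
    weights: Mapping[str, float] | Sequence[float] | None = None,
) -> float:
    """Total probability of injury P_I = 1 - prod_j w_j * (1 - NTCP_j).

    The weights w_j express relative clinical importance and multiply each
    survival factor inside the product, so a weight below 1 makes P_I
    positive even at zero NTCP; non-unit weights are accepted but flagged
    with a warning because of that semantics.
    """
    if isinstance(ntcps, Mapping):
        keys = list(ntcps)
        values = np.array([ntcps[k] for k in keys], dtype=float)
        if weights is None:
            w = np.ones_like(values)
        elif isinstance(weights, Mapping):
            w = np.array([weights.get(k, 1.0) for k in keys], dtype=float)
        else:
            w = np.asarray(weights, dtype=float)
    else:
        values = np.asarray(ntcps, dtype=float)
        w = np.ones_like(values) if weights is None else np.asarray(weights, dtype=float)
    if np.any((values < 0) | (values > 1)):
        raise ValueError("NTCP values must lie in [0, 1]")
    if np.any((w <= 0) | (w > 1)):
        raise ValueError("weights must lie in (0, 1]")
    if np.any(w < 1):
        warnings.warn(
            "non-unit weights make P_I > 0 even at zero NTCP", stacklevel=2
        )
    return float(1.0 - np.prod(w * (1.0 - values)))


def p_plus(tcp: float, p_injury: float) -> float:
    """Complication-free tumour control P+ = TCP * (1 - P_I).

    Valid under independence of tumour and normal-tissue response; always
    <= TCP, with equality iff P_I = 0.
    """
    if not (0 <= tcp <= 1 and 0 <= p_injury <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(tcp * (1.0 - p_injury))


def _inclusive_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Values lo, lo+step, ... up to hi inclusive, built as integer multiples."""
    if step <= 0:
        raise ValueError("step must be positive")
    if hi < lo:
        raise ValueError("range must be non-decreasing")
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def lkb_uncertainty_scan(
    dose: DoseGrid,
    organ: StructureMask,
    d50_range: tuple[float, float],
    d50_step: float,
    m_range: tuple[float, float],
    m_step: float,
    n: float,
    ab_ratio: float,
) -> pd.DataFrame:
    """NTCP over a Cartesian (D50, m) grid with inclusive endpoints.

    Returns a DataFrame with columns (d50, m, ntcp), one row per parameter
    combination; row count is the product of the two grid sizes.  The gEUD
    is computed once (it depends only on n and alpha/beta), then reused for
    every probit evaluation.
    """
    d50s = _inclusive_grid(*d50_range, d50_step)
    ms = _inclusive_grid(*m_range, m_step)
    if d50s.size == 0 or ms.size == 0:
        raise ValueError("step larger than range")
    from .models import geud  # local import to avoid cycle noise
    from scipy.special import ndtr

    eqd2 = voxel_eqd(dose, ab_ratio, reference_fraction_size=2.0)
    g = geud(eqd2.values[organ.occupancy], n)
    rows = [
        (d50, m, float(ndtr((g - d50) / (m * d50))))
        for d50 in d50s
        for m in ms
    ]
    return pd.DataFrame(rows, columns=["d50", "m", "ntcp"])


def alpha_beta_robustness(
    case: PlanCase,
    parameter_sets: Sequence[LQParams],
    target_role: Role = Role.GTV_HISTO,
) -> dict[str, float]:
    """TCP of one case under each tumour parameter set.

    Each set's alpha/beta enters the EQD0 conversion and its alpha the
    Poisson model; results are keyed by the set label (or index).
    """
    if not parameter_sets:
        raise ValueError("parameter_sets must be non-empty")
    target = case.structures.by_role(target_role)
    out = {}
    for i, ps in enumerate(parameter_sets):
        eqd0 = voxel_eqd(case.dose, ps.ab_ratio, reference_fraction_size=0.0)
        out[ps.label or f"set{i + 1}"] = tcp_poisson(eqd0, target, ps)
    return out
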