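"""Dose-response models: Poisson-LQ TCP, LKB NTCP, relative seriality.

All models act on isoeffect-converted voxel doses.  The tumour control
probability uses the zero-fraction-size equi-effective dose

    EQD0 = D * (1 + d / (alpha/beta)),

i.e. the biologically effective dose of the linear-quadratic model, while
both normal-tissue models use EQD2 (the isoeffective dose in 2 Gy
fractions) with the organ's own alpha/beta ratio.  TCP is the Poisson
probability that no clonogen survives,

    TCP = exp(-rho_cl * sum_i v_i * exp(-alpha * EQD0_i)),

with rho_cl the clonogenic cell density and v_i the voxel volume in cm^3.
The urethra NTCP is a Lyman-Kutcher-Burman probit in gEUD; bladder and
rectum use the Kallman relative-seriality model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr

from .grid import DoseGrid, StructureMask


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic tumour parameters.

    rho_cl : clonogen density, cells per cm^3
    alpha  : linear cell-kill coefficient, 1/Gy
    ab_ratio : tumour alpha/beta, Gy
    """

    rho_cl: float
    alpha: float
    ab_ratio: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.rho_cl <= 0 or self.alpha <= 0 or self.ab_ratio <= 0:
            raise ValueError("LQ parameters must be strictly positive")


@dataclass(frozen=True)
class LKBParams:
    """Lyman-Kutcher-Burman parameters (D50 Gy, slope m, volume exponent n)."""

    d50: float
    m: float
    n: float
    ab_ratio: float

    def __post_init__(self) -> None:
        if self.d50 <= 0 or self.m <= 0:
            raise ValueError("d50 and m must be positive")
        if not 0 < self.n <= 1:
            raise ValueError("volume exponent n must be in (0, 1]")
        if self.ab_ratio <= 0:
            raise ValueError("ab_ratio must be positive")


@dataclass(frozen=True)
class SerialityParams:
    """Relative-seriality parameters (D50 as EQD2, slope gamma, seriality s)."""

    d50: float
    gamma: float
    s: float
    ab_ratio: float

    def __post_init__(self) -> None:
        if min(self.d50, self.gamma, self.s, self.ab_ratio) <= 0:
            raise ValueError("seriality parameters must be strictly positive")


# ---------------------------------------------------------------------------
# isoeffect conversion


def eqd(
    total_dose: float | np.ndarray,
    dose_per_fraction: float | np.ndarray,
    ab_ratio: float,
    reference_fraction_size: float = 0.0,
) -> float | np.ndarray:
    """Isoeffective dose at a reference fraction size x (Gy).

    EQDx = D * (1 + d/(a/b)) / (1 + x/(a/b)); x = 0 gives the BED-style
    zero-fraction-size dose D * (1 + d/(a/b)).
    """
    if ab_ratio <= 0:
        raise ValueError("ab_ratio must be positive")
    if reference_fraction_size < 0:
        raise ValueError("reference fraction size must be >= 0")
    D = np.asarray(total_dose, dtype=float)
    d = np.asarray(dose_per_fraction, dtype=float)
    if np.any(D < 0) or np.any(d < 0):
        raise ValueError("doses must be non-negative")
    out = D * (1.0 + d / ab_ratio) / (1.0 + reference_fraction_size / ab_ratio)
    return float(out) if np.isscalar(total_dose) and np.isscalar(dose_per_fraction) else out


def voxel_eqd(
    dose: DoseGrid, ab_ratio: float, reference_fraction_size: float = 0.0
) -> DoseGrid:
    """Voxelwise isoeffect conversion using d_i = D_i / N per voxel."""
    if dose.n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    converted = eqd(
        dose.values, dose.values / dose.n_fractions, ab_ratio, reference_fraction_size
    )
    return dose.with_values(np.asarray(converted))


# ---------------------------------------------------------------------------
# tumour control


def tcp_poisson(eqd0: DoseGrid, target: StructureMask, params: LQParams) -> float:
    """Poisson-LQ tumour control probability over a target mask.

    ``eqd0`` must already be fraction-converted with the tumour alpha/beta.
    Accumulation happens in the log domain: log TCP is the sum over target
    voxels of ``-rho * v_i * exp(-alpha * EQD0_i)``.
    """
    if target.is_empty():
        raise ValueError(f"target {target.name!r} is empty")
    if not target.geometry.same_as(eqd0.geometry):
        raise ValueError("target and dose geometries differ")
    d = eqd0.values[target.occupancy]
    v = target.geometry.voxel_volume_cm3
    log_tcp = -params.rho_cl * v * np.sum(np.exp(-params.alpha * d))
    return float(np.exp(log_tcp))


def tcp_uniform(eqd0: float, volume_cm3: float, params: LQParams) -> float:
    """Closed-form TCP under uniform dose: exp(-rho * V * exp(-alpha*EQD0))."""
    return float(np.exp(-params.rho_cl * volume_cm3 * np.exp(-params.alpha * eqd0)))


def calibrate_alpha(
    volumes_cm3: list[float] | np.ndarray,
    schedule: tuple[float, float],
    ab_ratio: float,
    rho: float,
    target_tcp: float,
    aggregation: str = "mean",
    tol: float = 1e-8,
) -> float:
    """Fit alpha so a uniform-dose cohort reaches a target TCP.

    ``schedule`` is (total dose Gy, dose per fraction Gy); each volume
    receives that schedule uniformly, and ``aggregation`` decides whether
    the cohort-mean TCP ("mean") or every per-volume TCP ("per-volume",
    solved on the mean of per-volume alphas) is driven to the target.
    Solved by monotone bisection (Brent) to ``tol`` in alpha; the bracket
    widens automatically if the target lies outside it.
    """
    volumes = np.asarray(volumes_cm3, dtype=float)
    if volumes.size == 0:
        raise ValueError("volumes must be non-empty")
    if not 0 < target_tcp < 1:
        raise ValueError("target_tcp must be in (0, 1)")
    total, per_fx = schedule
    eqd0 = eqd(total, per_fx, ab_ratio, 0.0)

    def alpha_for_volume(v: float) -> float:
        # closed form: alpha = ln(rho*V / (-ln T)) / EQD0
        return float(np.log(rho * v / (-np.log(target_tcp))) / eqd0)

    if aggregation == "per-volume":
        return float(np.mean([alpha_for_volume(v) for v in volumes]))
    if aggregation != "mean":
        raise ValueError(f"unknown aggregation {aggregation!r}")

    def mean_tcp(alpha: float) -> float:
        return float(
            np.mean([np.exp(-rho * v * np.exp(-alpha * eqd0)) for v in volumes])
        )

    lo, hi = 1e-4, 1.0
    for _ in range(60):
        if mean_tcp(lo) < target_tcp < mean_tcp(hi):
            break
        lo /= 2
        hi *= 2
    else:
        raise RuntimeError("could not bracket the target TCP")
    return float(brentq(lambda a: mean_tcp(a) - target_tcp, lo, hi, xtol=tol))


# ---------------------------------------------------------------------------
# normal tissue


def geud(
    doses: np.ndarray, n: float, fractional_volumes: np.ndarray | None = None
) -> float:
    """Generalized equivalent uniform dose: (sum_i dv_i * D_i^(1/n))^n.

    Fractional volumes default to equal weights and must sum to 1.
    Computed in the log domain for numerical stability; the result lies in
    [min dose, max dose] and n = 1 gives the arithmetic mean exactly.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ValueError("empty dose list")
    if fractional_volumes is None:
        dv = np.full(doses.size, 1.0 / doses.size)
    else:
        dv = np.asarray(fractional_volumes, dtype=float)
        if not np.isclose(dv.sum(), 1.0, atol=1e-6):
            raise ValueError(f"fractional volumes sum to {dv.sum():g}, not 1")
    if not 0 < n <= 1:
        raise ValueError("n must be in (0, 1]")
    if n == 1:
        return float(np.sum(dv * doses))
    p = 1.0 / n
    # log-sum-exp over log(dv_i) + p*log(D_i); zero doses contribute nothing
    pos = doses > 0
    if not pos.any():
        return 0.0
    terms = np.log(dv[pos]) + p * np.log(doses[pos])
    m = terms.max()
    log_sum = m + np.log(np.sum(np.exp(terms - m)))
    return float(np.exp(n * log_sum))


def ntcp_lkb(dose: DoseGrid, organ: StructureMask, params: LKBParams) -> float:
    """LKB complication probability: Phi((gEUD - D50) / (m * D50)).

    Voxel doses are first converted to EQD2 with the organ's alpha/beta;
    Phi is the standard normal CDF evaluated via the error function.
    """
    if organ.is_empty():
        raise ValueError(f"organ {organ.name!r} is empty")
    eqd2 = voxel_eqd(dose, params.ab_ratio, reference_fraction_size=2.0)
    g = geud(eqd2.values[organ.occupancy], params.n)
    t = (g - params.d50) / (params.m * params.d50)
    return float(ndtr(t))


def seriality_response(dose: float | np.ndarray, d50: float, gamma: float):
    """Kallman per-voxel Poisson response P(D) = 2^(-exp(e*gamma*(1-D/D50))).

    Isolated here so an alternative dose-response shape can be substituted
    without touching the volume-combination rule.
    """
    D = np.asarray(dose, dtype=float)
    expo = np.e * gamma * (1.0 - D / d50)
    # exp(expo) overflows for very low doses; the response is then exactly 0
    with np.errstate(over="ignore"):
        out = np.exp2(-np.exp(expo))
    return float(out) if np.isscalar(dose) else out


def ntcp_relative_seriality(
    dose: DoseGrid, organ: StructureMask, params: SerialityParams
) -> float:
    """Relative-seriality NTCP on EQD2-converted voxel doses.

    NTCP = [1 - prod_i (1 - P(D_i)^s)^(dv_i)]^(1/s) with dv_i the fractional
    voxel volumes; s = 1 on a uniform full-volume dose reduces to P(D).
    The product is accumulated as a sum of logs.
    """
    if organ.is_empty():
        raise ValueError(f"organ {organ.name!r} is empty")
    eqd2 = voxel_eqd(dose, params.ab_ratio, reference_fraction_size=2.0)
    d = eqd2.values[organ.occupancy]
    dv = 1.0 / d.size
    p = seriality_response(d, params.d50, params.gamma)
    # log1p(-p^s); p^s can be 1 for extreme doses -> log 0, handled by clip
    ps = np.clip(np.power(p, params.s), 0.0, 1.0 - 1e-16)
    log_prod = dv * np.sum(np.log1p(-ps))
    inner = -np.expm1(log_prod)  # 1 - prod
    return float(np.clip(inner, 0.0, 1.0) ** (1.0 / params.s))
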