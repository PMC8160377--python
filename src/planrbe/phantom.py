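"""Seeded synthetic prostate-phantom cohorts with SIB dose distributions.

The generator emulates the geometry and dose statistics of a focal
dose-escalation planning study: a prostate with an embedded urethra and its
2 mm planning margin (PRV), an imaging-defined boost target (GTV-Union)
close to the urethra, a partially overlapping ground-truth tumour
(GTV-Histo) whose coverage by GTV-Union is controlled, bladder and rectum
neighbours, and three simultaneous-integrated-boost dose distributions of
60 Gy whole-prostate / 70 Gy boost in 20 fractions: plan 1 boosts the full
margin-expanded target, plan 2 additionally suppresses dose inside the
urethra, plan 3 inside the PRV.

Dose painting is analytic (level sets with Gaussian penumbrae plus a local
soft dose cap near the spared structure), not an optimizer run: the
pipeline evaluates dose distributions, it does not create them.  All
randomness flows from one integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grid import (
    DoseGrid,
    Geometry,
    PlanCase,
    Role,
    StructureMask,
    StructureSet,
    combine_masks,
    expand_mask,
)

PLAN_LABELS = ("plan1", "plan2", "plan3")


@dataclass(frozen=True)
class PhantomSpec:
    """All knobs of the phantom generator (lengths in mm, doses in Gy)."""

    spacing_mm: float = 1.5
    dims: tuple[int, int, int] = (64, 68, 56)

    prostate_semi_mm: tuple[float, float, float] = (23.0, 20.0, 21.0)
    urethra_xy_mm: tuple[float, float] = (0.0, 2.0)
    urethra_radius_mm: float = 3.0
    urethra_z_mm: tuple[float, float] = (-24.0, 24.0)
    prv_margin_mm: float = 2.0

    n_gtv: int = 2
    gtv_semi_mm: tuple[float, float, float] = (12.5, 10.5, 10.2)
    gtv_center_mm: tuple[float, float, float] = (12.0, -4.0, 1.0)
    gtv2_semi_mm: tuple[float, float, float] = (7.5, 6.5, 6.5)
    gtv2_center_mm: tuple[float, float, float] = (-11.5, 6.5, -3.0)
    histo_semi_mm: tuple[float, float, float] = (11.0, 10.0, 9.5)
    #: target coverage of GTV-Histo by GTV-Union (fraction of histo volume)
    histo_coverage: float = 0.79
    #: direction along which GTV-Histo is shifted out of GTV-Union to reach
    #: the coverage target (mostly caudo-cranial and away from the urethra)
    histo_shift_dir: tuple[float, float, float] = (0.45, -0.35, 0.82)
    #: upper bound on |GTV-Histo ∩ PRV| / |GTV-Histo|; the ground-truth
    #: tumour abuts but essentially never engulfs the urethral margin
    max_histo_prv_overlap: float = 0.01

    bladder_center_mm: tuple[float, float, float] = (0.0, -28.0, 26.0)
    bladder_semi_mm: tuple[float, float, float] = (22.0, 16.0, 14.0)
    rectum_center_y_mm: float = 31.0
    rectum_radius_mm: float = 12.0
    rectum_z_mm: tuple[float, float] = (-35.0, 35.0)

    ptv2_margin_mm: float = 5.0
    ptv3_margin_mm: float = 2.0

    base_dose_gy: float = 60.0
    boost_dose_gy: float = 70.0
    base_margin_mm: float = 12.0
    base_penumbra_mm: float = 2.5
    boost_margin_mm: float = 3.0
    boost_penumbra_mm: float = 2.0
    #: low-amplitude dose spill around the boost (fraction of the boost
    #: excess and its Gaussian reach), emulating the broad halo a
    #: simultaneous integrated boost leaves in the rest of the gland
    boost_spill_frac: float = 0.6
    boost_spill_sigma_mm: float = 8.0
    #: urethra / PRV D2% dose constraint the sparing plans are driven by
    sparing_target_d2_gy: float = 62.4
    #: the painter caps spared-structure dose at this fraction of the
    #: constraint, emulating the safety margin an optimizer leaves
    planning_margin_frac: float = 0.98
    #: sparing cap field shape: how fast the allowed maximum dose descends
    #: into the spared structure, rises again outside it, and its floor
    suppression_in_slope_gy_mm: float = 1.0
    suppression_out_slope_gy_mm: float = 3.0
    suppression_floor_gy: float = 59.0
    noise_sd_gy: float = 0.4
    noise_corr_mm: float = 8.0

    n_fractions: int = 20
    jitter_frac: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        if not 0 < self.histo_coverage <= 1:
            raise ValueError("histo_coverage must be in (0, 1]")
        if self.base_dose_gy >= self.boost_dose_gy:
            raise ValueError("base dose must be below boost dose")
        if self.n_gtv not in (1, 2):
            raise ValueError("n_gtv must be 1 or 2")

    @property
    def geometry(self) -> Geometry:
        sp = self.spacing_mm
        origin = tuple(-(d - 1) / 2.0 * sp for d in self.dims)
        return Geometry(origin, (sp, sp, sp), self.dims)


def _ellipsoid(geo: Geometry, center, semi) -> np.ndarray:
    X, Y, Z = geo.voxel_centers()
    return (
        ((X - center[0]) / semi[0]) ** 2
        + ((Y - center[1]) / semi[1]) ** 2
        + ((Z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _tube(geo: Geometry, xy, radius, z_range) -> np.ndarray:
    X, Y, Z = geo.voxel_centers()
    return (
        ((X - xy[0]) ** 2 + (Y - xy[1]) ** 2) <= radius**2
    ) & (Z >= z_range[0]) & (Z <= z_range[1])


def _place_histo(
    spec: PhantomSpec,
    geo: Geometry,
    union_occ: np.ndarray,
    prostate_occ: np.ndarray,
    urethra_occ: np.ndarray,
    prv_occ: np.ndarray,
) -> np.ndarray:
    """Shift the histo ellipsoid until its coverage by the union matches.

    Coverage(|histo ∩ union| / |histo|) decreases monotonically with the
    shift magnitude, so a bisection on the shift reaches the target within
    +-0.02 (well inside the +-0.05 contract).  Coverage 1.0 is realized by
    clipping the histo ellipsoid into the union.  The tumour never occupies
    the urethra lumen, and if its overlap with the PRV exceeds
    ``max_histo_prv_overlap`` the ellipsoid is pushed further out along the
    shift direction (overlap then takes precedence over coverage).
    """
    direction = np.asarray(spec.histo_shift_dir, dtype=float)
    direction = direction / np.linalg.norm(direction)
    base = np.asarray(spec.gtv_center_mm, dtype=float)

    def histo_at(t: float) -> np.ndarray:
        occ = _ellipsoid(geo, base + t * direction, spec.histo_semi_mm)
        return occ & prostate_occ & ~urethra_occ

    def coverage(occ: np.ndarray) -> float:
        n = occ.sum()
        return float((occ & union_occ).sum() / n) if n else 0.0

    def prv_overlap(occ: np.ndarray) -> float:
        n = occ.sum()
        return float((occ & prv_occ).sum() / n) if n else 0.0

    if spec.histo_coverage >= 1.0:
        occ = histo_at(0.0) & union_occ
        t = 0.0
    else:
        lo, hi = 0.0, 30.0
        if coverage(histo_at(lo)) < spec.histo_coverage:
            warnings.warn(
                "coverage target unreachable even without shift; using zero shift",
                stacklevel=2,
            )
        else:
            for _ in range(30):
                mid = (lo + hi) / 2
                if coverage(histo_at(mid)) >= spec.histo_coverage:
                    lo = mid
                else:
                    hi = mid
        t = lo
        occ = histo_at(t)
    while prv_overlap(occ) > spec.max_histo_prv_overlap and t < 40.0:
        t += 0.5
        occ = histo_at(t)
        if spec.histo_coverage >= 1.0:
            occ &= union_occ
    return occ


def make_phantom(spec: PhantomSpec) -> StructureSet:
    """Build the full structure set of one phantom case.

    Deterministic given the spec.  Produces prostate, urethra, PRV-urethra,
    GTV-Union (1-2 ellipsoids clipped to the prostate), GTV-Histo (placed to
    meet the coverage target), PTV2, the three boost volumes PTV3_1 (union
    + margin), PTV3_2 (minus urethra), PTV3_3 (minus PRV), bladder, rectum.
    """
    geo = spec.geometry
    prostate_occ = _ellipsoid(geo, (0.0, 0.0, 0.0), spec.prostate_semi_mm)
    prostate = StructureMask("prostate", Role.PROSTATE, geo, prostate_occ)
    if prostate.is_empty():
        raise ValueError("prostate does not fit on the grid")

    urethra = StructureMask(
        "urethra",
        Role.URETHRA,
        geo,
        _tube(geo, spec.urethra_xy_mm, spec.urethra_radius_mm, spec.urethra_z_mm),
    )
    prv = expand_mask(urethra, spec.prv_margin_mm, name="prv_urethra", role=Role.PRV_URETHRA)

    union_occ = _ellipsoid(geo, spec.gtv_center_mm, spec.gtv_semi_mm)
    if spec.n_gtv == 2:
        union_occ |= _ellipsoid(geo, spec.gtv2_center_mm, spec.gtv2_semi_mm)
    union_occ &= prostate_occ
    gtv_union = StructureMask("gtv_union", Role.GTV_UNION, geo, union_occ)
    if gtv_union.is_empty():
        raise ValueError("GTV-Union does not fit inside the prostate")

    histo_occ = _place_histo(
        spec, geo, union_occ, prostate_occ, urethra.occupancy, prv.occupancy
    )
    gtv_histo = StructureMask("gtv_histo", Role.GTV_HISTO, geo, histo_occ)

    ptv2 = expand_mask(prostate, spec.ptv2_margin_mm, name="ptv2", role=Role.PTV2)
    ptv3_1 = expand_mask(gtv_union, spec.ptv3_margin_mm, name="ptv3_1", role=Role.PTV3_1)
    ptv3_2 = combine_masks(ptv3_1, urethra, "difference", name="ptv3_2", role=Role.PTV3_2)
    ptv3_3 = combine_masks(ptv3_1, prv, "difference", name="ptv3_3", role=Role.PTV3_3)

    bladder = StructureMask(
        "bladder",
        Role.BLADDER,
        geo,
        _ellipsoid(geo, spec.bladder_center_mm, spec.bladder_semi_mm) & ~prostate_occ,
    )
    X, Y, Z = geo.voxel_centers()
    rectum_occ = (
        ((X - 0.0) ** 2 + (Y - spec.rectum_center_y_mm) ** 2)
        <= spec.rectum_radius_mm**2
    ) & (Z >= spec.rectum_z_mm[0]) & (Z <= spec.rectum_z_mm[1]) & ~prostate_occ
    rectum = StructureMask("rectum", Role.RECTUM, geo, rectum_occ)

    return StructureSet(
        [prostate, urethra, prv, gtv_union, gtv_histo, ptv2, ptv3_1, ptv3_2, ptv3_3,
         bladder, rectum]
    )


def _smooth_indicator(occ: np.ndarray, dilate_mm: float, sigma_mm: float, geo: Geometry) -> np.ndarray:
    """Gaussian-blurred indicator of a mask dilated by ``dilate_mm``."""
    if dilate_mm > 0:
        dist = ndimage.distance_transform_edt(~occ, sampling=geo.spacing)
        occ = dist <= dilate_mm * (1 + 1e-12)
    sigma_vox = [sigma_mm / s for s in geo.spacing]
    return ndimage.gaussian_filter(occ.astype(float), sigma=sigma_vox, mode="constant")


def paint_dose(
    structures: StructureSet,
    plan_label: str,
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
) -> DoseGrid:
    """Paint one plan's dose distribution onto the phantom grid.

    The base prescription is a blurred plateau over the margin-expanded
    prostate, the boost a blurred plateau over the plan's boost volume
    plus a broad low-amplitude spill halo, plus spatially correlated
    noise.  For plan 2 (urethra) and plan 3 (PRV-urethra) the dose is
    clipped against a spatial maximum-dose field that equals
    ``planning_margin_frac`` times the D2% constraint at the spared
    structure's surface, descends into its interior
    (``suppression_in_slope_gy_mm``, floored at ``suppression_floor_gy``)
    and rises steeply outside it (``suppression_out_slope_gy_mm``) —
    the shape an optimizer realizes when the boost target excludes the
    spared structure but nothing else.
    """
    from .grid import BOOST_ROLE

    if plan_label not in BOOST_ROLE:
        raise ValueError(f"unknown plan label {plan_label!r}")
    geo = next(iter(structures)).geometry
    boost = structures.by_role(BOOST_ROLE[plan_label])
    prostate = structures.by_role(Role.PROSTATE)

    base_field = _smooth_indicator(
        prostate.occupancy, spec.base_margin_mm, spec.base_penumbra_mm, geo
    )
    boost_field = _smooth_indicator(
        boost.occupancy, spec.boost_margin_mm, spec.boost_penumbra_mm, geo
    )
    halo = ndimage.gaussian_filter(
        boost.occupancy.astype(float),
        sigma=[spec.boost_spill_sigma_mm / s for s in geo.spacing],
        mode="constant",
    )
    boost_mix = np.clip(boost_field + spec.boost_spill_frac * halo, 0.0, 1.0)
    dose = spec.base_dose_gy * base_field
    dose += (spec.boost_dose_gy - spec.base_dose_gy) * np.minimum(
        boost_mix, base_field
    )

    if spec.noise_sd_gy > 0:
        if rng is None:
            plan_index = PLAN_LABELS.index(plan_label)
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, 7919 + plan_index])
            )
        white = rng.standard_normal(geo.dims)
        sigma_vox = [spec.noise_corr_mm / s for s in geo.spacing]
        smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="constant")
        smooth *= spec.noise_sd_gy / smooth.std()
        dose += smooth * np.clip(base_field, 0.0, 1.0)

    spared_role = {"plan2": Role.URETHRA, "plan3": Role.PRV_URETHRA}.get(plan_label)
    if spared_role is not None:
        spared = structures.by_role(spared_role).occupancy
        d_out = ndimage.distance_transform_edt(~spared, sampling=geo.spacing)
        d_in = ndimage.distance_transform_edt(spared, sampling=geo.spacing)
        cap = spec.planning_margin_frac * spec.sparing_target_d2_gy
        cap_field = np.maximum(
            cap
            - spec.suppression_in_slope_gy_mm * d_in
            + spec.suppression_out_slope_gy_mm * d_out,
            spec.suppression_floor_gy,
        )
        dose = np.minimum(dose, cap_field)

    return DoseGrid(geo, np.maximum(dose, 0.0), spec.n_fractions)


def _jitter_spec(template: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Per-case geometry drawn around the template.

    A global tumour size factor (uniform within +-30% in volume), per-axis
    semi-axis jitter, a few mm of target displacement, and a coverage target
    drawn from a clipped normal around the template's value.
    """
    j = template.jitter_frac

    def ax_jitter(semi):
        size = rng.uniform(0.7, 1.3) ** (1 / 3)
        return tuple(s * size * rng.uniform(1 - j, 1 + j) for s in semi)

    center = tuple(
        c + rng.uniform(-2.0, 2.0) for c in template.gtv_center_mm
    )
    coverage = float(
        np.clip(rng.normal(template.histo_coverage, 0.10), 0.55, 0.98)
    )
    return replace(
        template,
        gtv_semi_mm=ax_jitter(template.gtv_semi_mm),
        histo_semi_mm=ax_jitter(template.histo_semi_mm),
        gtv_center_mm=center,
        histo_coverage=coverage,
        prostate_semi_mm=tuple(
            s * rng.uniform(1 - j / 2, 1 + j / 2) for s in template.prostate_semi_mm
        ),
    )


def make_cohort(
    n_cases: int,
    template: PhantomSpec | None = None,
    seed: int | None = None,
    plans: tuple[str, ...] = PLAN_LABELS,
) -> list[PlanCase]:
    """Generate ``n_cases`` phantom patients x the requested plans.

    Per-case geometry is jittered from the template by seeded draws; the
    same seed reproduces the identical cohort.  Returns a flat list of
    PlanCases (case ``case01``..., plans in the given order).
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    template = template or PhantomSpec()
    seed = template.seed if seed is None else seed
    cohort: list[PlanCase] = []
    for i in range(n_cases):
        case_rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        spec = _jitter_spec(replace(template, seed=seed), case_rng)
        structures = make_phantom(spec)
        for plan in plans:
            noise_rng = np.random.default_rng(
                np.random.SeedSequence([seed, i, PLAN_LABELS.index(plan)])
            )
            dose = paint_dose(structures, plan, spec, rng=noise_rng)
            cohort.append(PlanCase(f"case{i + 1:02d}", plan, dose, structures))
    return cohort
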