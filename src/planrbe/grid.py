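"""Dose grids, structure masks and plan cases.

All geometry is an axis-aligned patient grid with axes ordered
(left-right, anterior-posterior, cranio-caudal), millimetre units, and a
voxel-centre convention: ``origin`` is the physical position of the centre
of voxel ``(0, 0, 0)``.  Arrays are indexed ``values[ix, iy, iz]``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from scipy import ndimage

CASE_FORMAT_VERSION = 1


class Role(str, Enum):
    """Structure role labels used throughout the pipeline."""

    GTV_HISTO = "GTV_HISTO"
    GTV_UNION = "GTV_UNION"
    GTV_PET = "GTV_PET"
    GTV_MRI = "GTV_MRI"
    PROSTATE = "PROSTATE"
    URETHRA = "URETHRA"
    PRV_URETHRA = "PRV_URETHRA"
    BLADDER = "BLADDER"
    RECTUM = "RECTUM"
    PTV1 = "PTV1"
    PTV2 = "PTV2"
    PTV3_1 = "PTV3_1"
    PTV3_2 = "PTV3_2"
    PTV3_3 = "PTV3_3"
    OTHER = "OTHER"


@dataclass(frozen=True)
class Geometry:
    """Shared grid geometry: origin (mm), spacing (mm), dims (voxels)."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.dims) != 3:
            raise ValueError("origin, spacing and dims must be length-3")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be >= 1, got {self.dims}")

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis (mm)."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(*(self.axis_coords(a) for a in range(3)), indexing="ij")

    def same_as(self, other: "Geometry", tol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )


@dataclass
class DoseGrid:
    """3D matrix of total physical dose in Gy over a fractionation schedule.

    ``values[ix, iy, iz]`` holds the total dose D delivered in
    ``n_fractions`` fractions; the per-voxel dose per fraction is
    ``D / n_fractions``.
    """

    geometry: Geometry
    values: np.ndarray
    n_fractions: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.dims:
            raise ValueError(
                f"values shape {self.values.shape} != geometry dims {self.geometry.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")

    @property
    def dose_per_fraction(self) -> np.ndarray:
        return self.values / self.n_fractions

    def with_values(self, values: np.ndarray) -> "DoseGrid":
        return DoseGrid(self.geometry, values, self.n_fractions)


@dataclass
class StructureMask:
    """Boolean occupancy of one structure on a reference geometry."""

    name: str
    role: Role
    geometry: Geometry
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.shape != self.geometry.dims:
            raise ValueError(
                f"mask shape {self.occupancy.shape} != geometry dims {self.geometry.dims}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * self.geometry.voxel_volume_cm3

    def is_empty(self) -> bool:
        return self.voxel_count == 0


class StructureSet:
    """Named masks sharing one geometry, addressable by name or role."""

    def __init__(self, masks: Iterable[StructureMask] = ()):
        self._masks: dict[str, StructureMask] = {}
        for m in masks:
            self.add(m)

    def add(self, mask: StructureMask) -> None:
        if self._masks:
            ref = next(iter(self._masks.values())).geometry
            if not mask.geometry.same_as(ref):
                raise ValueError(f"mask {mask.name!r} geometry differs from the set's")
        self._masks[mask.name] = mask

    def __getitem__(self, name: str) -> StructureMask:
        return self._masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self._masks

    def __iter__(self):
        return iter(self._masks.values())

    def __len__(self) -> int:
        return len(self._masks)

    @property
    def names(self) -> list[str]:
        return list(self._masks)

    def by_role(self, role: Role) -> StructureMask:
        hits = [m for m in self._masks.values() if m.role == role]
        if not hits:
            raise KeyError(f"no structure with role {role.value}")
        if len(hits) > 1:
            raise KeyError(f"multiple structures with role {role.value}")
        return hits[0]

    def has_role(self, role: Role) -> bool:
        return any(m.role == role for m in self._masks.values())


PlanLabel = Literal["plan1", "plan2", "plan3"]
#: boost volume used for the simultaneous integrated boost of each plan
BOOST_ROLE: dict[str, Role] = {
    "plan1": Role.PTV3_1,
    "plan2": Role.PTV3_2,
    "plan3": Role.PTV3_3,
}


@dataclass
class PlanCase:
    """One patient's dose distribution, structures and plan label."""

    case_id: str
    plan_label: str
    dose: DoseGrid
    structures: StructureSet

    def __post_init__(self) -> None:
        if self.plan_label not in BOOST_ROLE:
            raise ValueError(f"unknown plan label {self.plan_label!r}")
        for m in self.structures:
            if not m.geometry.same_as(self.dose.geometry):
                raise ValueError(
                    f"structure {m.name!r} geometry differs from the dose grid"
                )


Cohort = list


# ---------------------------------------------------------------------------
# geometry operations


def resample_to(grid: DoseGrid, target: Geometry) -> DoseGrid:
    """Trilinear resampling of a dose grid onto a target geometry.

    Target voxel centres outside the source support receive 0 Gy (with a
    warning).  Identity geometries return a copy with bitwise-equal values.
    """
    if grid.geometry.same_as(target):
        return DoseGrid(target, grid.values.copy(), grid.n_fractions)

    src = grid.geometry
    # fractional source-index coordinates of the target voxel centres
    coords = []
    outside = np.zeros(target.dims, dtype=bool)
    for ax in range(3):
        t = target.axis_coords(ax)
        idx = (t - src.origin[ax]) / src.spacing[ax]
        lo, hi = 0.0, src.dims[ax] - 1.0
        out_ax = (idx < lo - 1e-9) | (idx > hi + 1e-9)
        shape = [1, 1, 1]
        shape[ax] = target.dims[ax]
        outside |= out_ax.reshape(shape)
        coords.append(np.clip(idx, lo, hi))
    mesh = np.meshgrid(*coords, indexing="ij")
    values = ndimage.map_coordinates(
        grid.values, [m.ravel() for m in mesh], order=1, mode="nearest"
    ).reshape(target.dims)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} target voxels fall outside the source support; "
            "set to 0 Gy",
            stacklevel=2,
        )
        values[outside] = 0.0
    return DoseGrid(target, values, grid.n_fractions)


def expand_mask(
    mask: StructureMask,
    margin_mm: float,
    name: str | None = None,
    role: Role | None = None,
) -> StructureMask:
    """Morphological dilation by a Euclidean ball of radius ``margin_mm``.

    A voxel belongs to the result iff its centre lies within ``margin_mm`` of
    some input voxel centre; anisotropic spacing is respected.  Margin 0 is
    the identity.
    """
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    new_name = name if name is not None else f"{mask.name}+{margin_mm:g}mm"
    new_role = role if role is not None else mask.role
    if margin_mm == 0 or mask.is_empty():
        occ = mask.occupancy.copy()
    else:
        dist = ndimage.distance_transform_edt(
            ~mask.occupancy, sampling=mask.geometry.spacing
        )
        occ = dist <= margin_mm * (1 + 1e-12)
    return StructureMask(new_name, new_role, mask.geometry, occ)


def combine_masks(
    a: StructureMask,
    b: StructureMask,
    op: Literal["union", "intersection", "difference"],
    name: str | None = None,
    role: Role = Role.OTHER,
) -> StructureMask:
    """Voxelwise boolean combination of two masks on the same geometry."""
    if not a.geometry.same_as(b.geometry):
        raise ValueError("masks have different geometries")
    if op == "union":
        occ = a.occupancy | b.occupancy
    elif op == "intersection":
        occ = a.occupancy & b.occupancy
    elif op == "difference":
        occ = a.occupancy & ~b.occupancy
    else:
        raise ValueError(f"unknown op {op!r}")
    return StructureMask(name or f"{a.name}_{op}_{b.name}", role, a.geometry, occ)


# ---------------------------------------------------------------------------
# internal case bundle: case.json + one .npz payload per case


def write_case(case: PlanCase, path: str | Path) -> None:
    """Write a case bundle: ``case.json`` header + ``arrays.npz`` payload.

    The header records geometry, schedule, structure names/roles and the
    format version; the payload holds the dose array (float64, row-major,
    dims as in the header) and one packed boolean array per structure.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    geo = case.dose.geometry
    header = {
        "format_version": CASE_FORMAT_VERSION,
        "case_id": case.case_id,
        "plan_label": case.plan_label,
        "origin_mm": list(geo.origin),
        "spacing_mm": list(geo.spacing),
        "dims": list(geo.dims),
        "n_fractions": case.dose.n_fractions,
        "structures": [
            {"name": m.name, "role": m.role.value} for m in case.structures
        ],
        "array_order": "row-major (ix, iy, iz) = (LR, AP, CC)",
    }
    (path / "case.json").write_text(json.dumps(header, indent=2))
    arrays = {"dose": case.dose.values}
    for m in case.structures:
        arrays[f"mask:{m.name}"] = np.packbits(m.occupancy.ravel())
    np.savez_compressed(path / "arrays.npz", **arrays)


def read_case(path: str | Path) -> PlanCase:
    """Read a case bundle written by :func:`write_case` (lossless)."""
    path = Path(path)
    header = json.loads((path / "case.json").read_text())
    version = header.get("format_version")
    if version != CASE_FORMAT_VERSION:
        raise ValueError(
            f"unsupported case format version {version!r} "
            f"(expected {CASE_FORMAT_VERSION})"
        )
    for key in ("origin_mm", "spacing_mm", "dims", "n_fractions"):
        if key not in header:
            raise ValueError(f"case header missing required field {key!r}")
    geo = Geometry(
        tuple(header["origin_mm"]), tuple(header["spacing_mm"]), tuple(header["dims"])
    )
    with np.load(path / "arrays.npz") as arrays:
        dose = DoseGrid(geo, arrays["dose"], header["n_fractions"])
        n_vox = int(np.prod(geo.dims))
        masks = []
        for entry in header["structures"]:
            bits = np.unpackbits(arrays[f"mask:{entry['name']}"], count=n_vox)
            occ = bits.astype(bool).reshape(geo.dims)
            masks.append(StructureMask(entry["name"], Role(entry["role"]), geo, occ))
    return PlanCase(header["case_id"], header["plan_label"], dose, StructureSet(masks))


def write_cohort(cohort: Iterable[PlanCase], root: str | Path) -> list[Path]:
    root = Path(root)
    paths = []
    for case in cohort:
        p = root / f"{case.case_id}_{case.plan_label}"
        write_case(case, p)
        paths.append(p)
    return paths


def read_cohort(root: str | Path) -> list[PlanCase]:
    root = Path(root)
    return [read_case(p.parent) for p in sorted(root.glob("*/case.json"))]
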