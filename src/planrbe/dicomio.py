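"""DICOM RT Dose / RT Structure Set readers and minimal writers.

One common dialect is supported: axis-aligned HFS grids
(ImageOrientationPatient ``[1,0,0,0,1,0]``), a uniform GridFrameOffsetVector
and a DoseGridScaling factor.  Oblique orientations are rejected rather
than silently resampled.  The writers exist to produce round-trippable
fixtures in the same dialect; they are not a full planning-system export.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pydicom
from matplotlib.path import Path as MplPath
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .grid import DoseGrid, Geometry, Role, StructureMask, StructureSet

_RTDOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"
_RTSTRUCT_SOP = "1.2.840.10008.5.1.4.1.1.481.3"
_AXIAL_ORIENTATION = [1.0, 0.0, 0.0, 0.0, 1.0, 0.0]


def read_rt_dose(path: str | Path) -> DoseGrid:
    """Read an RT Dose object into a :class:`DoseGrid` (values in Gy).

    Stored integers are multiplied by DoseGridScaling; axis order is
    normalized from DICOM's (frame, row, col) to (LR, AP, CC).
    """
    ds = pydicom.dcmread(str(path))
    if ds.SOPClassUID != _RTDOSE_SOP:
        raise ValueError(f"not an RT Dose object: SOP class {ds.SOPClassUID}")
    orient = [float(v) for v in ds.ImageOrientationPatient]
    if not np.allclose(orient, _AXIAL_ORIENTATION):
        raise ValueError(f"only axis-aligned HFS grids are supported, got {orient}")
    if "DoseGridScaling" not in ds:
        raise ValueError("RT Dose is missing DoseGridScaling")
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    if len(offsets) < 2:
        raise ValueError("GridFrameOffsetVector must have >= 2 frames")
    steps = np.diff(offsets)
    if not np.allclose(steps, steps[0], atol=1e-6):
        raise ValueError(f"non-uniform frame offsets: steps {np.unique(steps)}")
    dz = float(steps[0])
    if dz <= 0:
        raise ValueError("frame offsets must be increasing")
    row_mm, col_mm = (float(v) for v in ds.PixelSpacing)  # (AP, LR)
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    scaling = float(ds.DoseGridScaling)
    arr = ds.pixel_array.astype(np.float64) * scaling  # (frames, rows, cols)
    values = np.ascontiguousarray(arr.transpose(2, 1, 0))  # -> (LR, AP, CC)
    geo = Geometry(origin, (col_mm, row_mm, dz), values.shape)
    n_fx = int(getattr(ds, "NumberOfFractionsPlanned", 0)) or 1
    return DoseGrid(geo, values, n_fx)


def write_rt_dose(
    dose: DoseGrid, path: str | Path, scaling: float = 1e-3
) -> None:
    """Write a DoseGrid as a 32-bit RT Dose file in the supported dialect."""
    geo = dose.geometry
    stored = np.round(dose.values / scaling)
    if stored.max() >= 2**32:
        raise ValueError("dose exceeds 32-bit range at this scaling")
    arr = stored.astype(np.uint32).transpose(2, 1, 0)  # (CC, AP, LR)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTDOSE_SOP
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = _RTDOSE_SOP
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.ImageOrientationPatient = _AXIAL_ORIENTATION
    ds.ImagePositionPatient = [float(v) for v in geo.origin]
    ds.PixelSpacing = [geo.spacing[1], geo.spacing[0]]  # (row=AP, col=LR)
    ds.GridFrameOffsetVector = [geo.spacing[2] * k for k in range(geo.dims[2])]
    ds.NumberOfFrames = geo.dims[2]
    ds.Rows = geo.dims[1]
    ds.Columns = geo.dims[0]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseGridScaling = scaling
    ds.NumberOfFractionsPlanned = dose.n_fractions
    ds.PixelData = np.ascontiguousarray(arr).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def _rasterize_contour(points_xy: np.ndarray, geo: Geometry) -> np.ndarray:
    """Even-odd inside test of voxel centres on one axial slice.

    Returns a 2D boolean array over (LR, AP).  Boundary points count as
    inside (a tiny positive path radius is used).
    """
    xs = geo.axis_coords(0)
    ys = geo.axis_coords(1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    verts = np.vstack([points_xy, points_xy[:1]])
    codes = np.full(len(verts), MplPath.LINETO, dtype=np.uint8)
    codes[0] = MplPath.MOVETO
    codes[-1] = MplPath.CLOSEPOLY
    path = MplPath(verts, codes)
    inside = path.contains_points(pts, radius=1e-7)
    return inside.reshape(len(xs), len(ys))


def rasterize_contours(
    contours: Sequence[tuple[float, np.ndarray]],
    geo: Geometry,
    roi_name: str = "",
) -> np.ndarray:
    """Rasterize planar contours ``(z_mm, Nx2 xy points)`` to a 3D mask.

    Slices are matched by nearest CC coordinate within half a CC spacing.
    Multiple contours on one slice combine by XOR (even-odd rule, so holes
    subtract).  Contours lying outside the grid raise; degenerate contours
    (< 3 points) are skipped with a warning.
    """
    occ = np.zeros(geo.dims, dtype=bool)
    zs = geo.axis_coords(2)
    half_dz = geo.spacing[2] / 2
    x_lo, x_hi = geo.axis_coords(0)[[0, -1]]
    y_lo, y_hi = geo.axis_coords(1)[[0, -1]]
    for z, pts in contours:
        pts = np.asarray(pts, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 3:
            warnings.warn(
                f"degenerate contour ({pts.shape[0]} points) in ROI {roi_name!r}; "
                "skipped",
                stacklevel=2,
            )
            continue
        iz = int(np.argmin(np.abs(zs - z)))
        if abs(zs[iz] - z) > half_dz * (1 + 1e-9):
            raise ValueError(
                f"contour of ROI {roi_name!r} at z={z:g} mm lies outside the grid"
            )
        # allow contours to touch the outer half-voxel band but not leave it
        if (
            pts[:, 0].min() < x_lo - geo.spacing[0]
            or pts[:, 0].max() > x_hi + geo.spacing[0]
            or pts[:, 1].min() < y_lo - geo.spacing[1]
            or pts[:, 1].max() > y_hi + geo.spacing[1]
        ):
            raise ValueError(f"contour of ROI {roi_name!r} extends outside the grid")
        occ[:, :, iz] ^= _rasterize_contour(pts[:, :2], geo)
    return occ


def read_rt_struct(
    path: str | Path,
    ref: DoseGrid | Geometry,
    roles: Mapping[str, Role] | None = None,
) -> StructureSet:
    """Read an RT Structure Set and rasterize each ROI onto ``ref``'s grid.

    ``roles`` maps ROI names to :class:`Role`; unmapped ROIs get
    ``Role.OTHER``.  Empty ROIs yield an empty mask with a warning.
    """
    geo = ref.geometry if isinstance(ref, DoseGrid) else ref
    ds = pydicom.dcmread(str(path))
    if ds.SOPClassUID != _RTSTRUCT_SOP:
        raise ValueError(f"not an RT Structure Set: SOP class {ds.SOPClassUID}")
    names = {
        int(roi.ROINumber): str(roi.ROIName)
        for roi in ds.StructureSetROISequence
    }
    roles = roles or {}
    masks = []
    for rc in ds.ROIContourSequence:
        name = names[int(rc.ReferencedROINumber)]
        contours: list[tuple[float, np.ndarray]] = []
        for c in getattr(rc, "ContourSequence", []):
            data = np.asarray([float(v) for v in c.ContourData]).reshape(-1, 3)
            contours.append((float(data[0, 2]), data[:, :2]))
        occ = rasterize_contours(contours, geo, roi_name=name)
        if not occ.any():
            warnings.warn(f"ROI {name!r} rasterized to an empty mask", stacklevel=2)
        masks.append(StructureMask(name, roles.get(name, Role.OTHER), geo, occ))
    return StructureSet(masks)


def write_rt_struct(
    contours_by_roi: Mapping[str, Sequence[tuple[float, np.ndarray]]],
    path: str | Path,
) -> None:
    """Write planar contours as a minimal RT Structure Set fixture."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTSTRUCT_SOP
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = _RTSTRUCT_SOP
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for number, (name, contours) in enumerate(contours_by_roi.items(), start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = generate_uid()
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = []
        for z, pts in contours:
            c = Dataset()
            pts = np.asarray(pts, dtype=float)
            data = np.column_stack([pts, np.full(len(pts), z)])
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(pts)
            c.ContourData = [float(v) for v in data.ravel()]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
    ds.save_as(str(path), enforce_file_format=True)
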