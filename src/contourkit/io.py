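"""File formats: NIfTI volumes/masks, DICOM CT series, DICOM RT-STRUCT.

NIfTI is the canonical on-disk format; DICOM RT Structure Sets are supported
for import/export only (planar contour polygons referencing a CT series),
with :func:`rasterize` converting contour polygons to binary masks on a
voxel grid and :func:`mask_to_structure_set` going the other way.

Only axis-aligned geometries are supported: NIfTI affines must be diagonal
with positive spacing, and DICOM series must use the identity in-plane
orientation.  Anything else raises :class:`OrientationError` rather than
silently reinterpreting coordinates.

Rasterization rule
------------------
A voxel belongs to a polygon when its centre is strictly inside, or on the
lower-x / lower-y edge, by the even-odd (crossing-number) rule; multiple
polygons on one slice combine by parity, so holes subtract.  The rule is
deterministic across platforms; exact boundary-voxel counts may differ from
other software by the boundary convention.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from skimage import measure

from .core import BinaryMask, GridError, ImageVolume, StructureSet, VoxelGrid

__all__ = [
    "OrientationError",
    "ManifestError",
    "read_image_nifti",
    "read_mask_nifti",
    "write_image_nifti",
    "write_mask_nifti",
    "read_ct_series",
    "write_ct_series",
    "read_rtstruct",
    "write_rtstruct",
    "rasterize",
    "mask_to_structure_set",
    "read_manifest",
    "write_manifest",
    "MANIFEST_COLUMNS",
]

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("case", "structure", "role", "path", "format")

CT_STORAGE = "1.2.840.10008.5.1.4.1.1.2"
RTSTRUCT_STORAGE = "1.2.840.10008.5.1.4.1.1.481.3"


class OrientationError(GridError):
    """Non-axis-aligned image orientation."""


class ManifestError(ValueError):
    """Malformed or inconsistent case manifest."""


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _grid_from_affine(affine: np.ndarray, shape: tuple[int, ...], path) -> VoxelGrid:
    rot = affine[:3, :3]
    diag = np.diag(rot)
    off = rot - np.diag(diag)
    if np.abs(off).max() > 1e-6 or np.any(diag <= 0):
        raise OrientationError(
            f"{path}: only axis-aligned affines with positive spacing are supported "
            f"(got rotation/scale block {rot.tolist()})"
        )
    if len(shape) != 3:
        raise GridError(f"{path}: expected a 3-D volume, got shape {shape}")
    return VoxelGrid(tuple(shape), tuple(diag), tuple(affine[:3, 3]))


def _affine_from_grid(grid: VoxelGrid) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing)
    affine[:3, 3] = grid.origin
    return affine


def read_image_nifti(path) -> ImageVolume:
    """Load a scalar NIfTI volume; spacing/origin from the (diagonal) affine."""
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape, path)
    data = np.asanyarray(img.dataobj)
    return ImageVolume(grid, data)


def read_mask_nifti(path, threshold: float = 0.5, label: str = "", source: str = "") -> BinaryMask:
    """Load a NIfTI label/probability volume as a binary mask (values > threshold)."""
    vol = read_image_nifti(path)
    occ = np.asarray(vol.intensities) > threshold
    if not occ.any():
        logger.warning("mask file %s is empty after thresholding at %g", path, threshold)
    return BinaryMask(vol.grid, occ, label=label, source=source)


def write_image_nifti(volume: ImageVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.intensities), _affine_from_grid(volume.grid))
    nib.save(img, str(path))


def write_mask_nifti(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(
        mask.occupancy.astype(np.uint8), _affine_from_grid(mask.grid)
    )
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# DICOM CT series
# ---------------------------------------------------------------------------

def _read_series_datasets(ct_dir) -> list[Dataset]:
    paths = sorted(Path(ct_dir).glob("*.dcm"))
    if not paths:
        raise IOError(f"no .dcm files found in {ct_dir}")
    dsets = [pydicom.dcmread(str(p)) for p in paths]
    dsets = [d for d in dsets if getattr(d, "Modality", "") == "CT"]
    if not dsets:
        raise IOError(f"no CT slices found in {ct_dir}")
    dsets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    return dsets


def read_ct_series(ct_dir) -> ImageVolume:
    """Read an axis-aligned single-frame DICOM CT series (HU after rescale)."""
    dsets = _read_series_datasets(ct_dir)
    first = dsets[0]
    iop = np.asarray(first.ImageOrientationPatient, dtype=float)
    if np.abs(iop - np.array([1, 0, 0, 0, 1, 0])).max() > 1e-6:
        raise OrientationError(
            f"{ct_dir}: only identity in-plane orientation is supported (got {iop.tolist()})"
        )
    zs = np.array([float(d.ImagePositionPatient[2]) for d in dsets])
    dz = np.diff(zs)
    if len(dz) and (dz.max() - dz.min()) > 1e-3:
        raise GridError(f"{ct_dir}: non-uniform slice spacing {sorted(set(np.round(dz, 4)))}")
    sz = float(dz[0]) if len(dz) else float(getattr(first, "SliceThickness", 1.0))
    row_sp, col_sp = (float(v) for v in first.PixelSpacing)  # (y, x)
    slices = []
    for d in dsets:
        arr = d.pixel_array.astype(float)
        arr = arr * float(getattr(d, "RescaleSlope", 1.0)) + float(
            getattr(d, "RescaleIntercept", 0.0)
        )
        slices.append(arr.T)  # (rows=y, cols=x) -> (x, y)
    vol = np.stack(slices, axis=-1)
    origin = tuple(float(v) for v in first.ImagePositionPatient)
    grid = VoxelGrid(vol.shape, (col_sp, row_sp, sz), origin)
    return ImageVolume(grid, vol)


def write_ct_series(volume: ImageVolume, ct_dir, patient_id: str = "PHANTOM") -> list[Path]:
    """Write a minimal single-frame CT series (synthetic; int16 HU slices).

    Intended for phantoms and round-trip tests — intensities are rounded to
    whole HU.  Returns the written slice paths in z order.
    """
    ct_dir = Path(ct_dir)
    ct_dir.mkdir(parents=True, exist_ok=True)
    grid = volume.grid
    study_uid = generate_uid()
    series_uid = generate_uid()
    frame_uid = generate_uid()
    data = np.rint(np.asarray(volume.intensities)).astype(np.int16)
    paths = []
    for k in range(grid.shape[2]):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = CT_STORAGE
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = CT_STORAGE
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.PatientName = patient_id
        ds.PatientID = patient_id
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            grid.origin[0],
            grid.origin[1],
            grid.origin[2] + k * grid.spacing[2],
        ]
        ds.PixelSpacing = [grid.spacing[1], grid.spacing[0]]  # (row=y, col=x)
        ds.SliceThickness = grid.spacing[2]
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = grid.shape[1], grid.shape[0]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.PixelData = np.ascontiguousarray(data[:, :, k].T).tobytes()
        path = ct_dir / f"ct_{k:04d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# RT-STRUCT
# ---------------------------------------------------------------------------

def read_rtstruct(
    ct_dir,
    rtstruct_path,
    aliases: Mapping[str, str] | None = None,
) -> StructureSet:
    """Read an RT Structure Set referencing the CT series in ``ct_dir``.

    Each ROI becomes a list of ``(z, polygon)`` planar contours in mm.
    ROI names pass through verbatim, optionally renamed via ``aliases``
    (raw name -> canonical name); polygons with fewer than 3 points are
    skipped with a warning.  A frame-of-reference mismatch with the CT is an
    error.
    """
    ct_first = _read_series_datasets(ct_dir)[0]
    ds = pydicom.dcmread(str(rtstruct_path))
    frame = _rtstruct_frame_uid(ds)
    if frame and str(ct_first.FrameOfReferenceUID) != frame:
        raise ValueError(
            f"RT-STRUCT frame of reference {frame} does not match the CT series "
            f"({ct_first.FrameOfReferenceUID})"
        )
    names = {
        int(roi.ROINumber): str(roi.ROIName) for roi in ds.StructureSetROISequence
    }
    structures: dict[str, list[tuple[float, np.ndarray]]] = {}
    for rc in getattr(ds, "ROIContourSequence", []):
        name = names.get(int(rc.ReferencedROINumber), f"ROI-{rc.ReferencedROINumber}")
        if aliases:
            name = aliases.get(name, name)
        polys = structures.setdefault(name, [])
        for contour in getattr(rc, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            if pts.shape[0] < 3:
                logger.warning(
                    "ROI %r: skipping a contour with %d point(s)", name, pts.shape[0]
                )
                continue
            polys.append((float(pts[0, 2]), pts[:, :2].copy()))
    return StructureSet(frame_of_reference=frame, structures=structures)


def _rtstruct_frame_uid(ds: Dataset) -> str:
    for ref in getattr(ds, "ReferencedFrameOfReferenceSequence", []):
        return str(ref.FrameOfReferenceUID)
    return str(getattr(ds, "FrameOfReferenceUID", ""))


def write_rtstruct(structures, ct_dir, path) -> None:
    """Write a minimal RT Structure Set referencing the CT series in ``ct_dir``.

    ``structures`` is a :class:`StructureSet` or a mapping of structure name
    to :class:`BinaryMask` (masks are converted to per-slice contours first).
    Contour coordinates round-trip with :func:`read_rtstruct` to well below
    1e-3 mm.  An empty structure collection is an error.
    """
    if isinstance(structures, dict):
        converted: dict[str, list[tuple[float, np.ndarray]]] = {}
        for name, mask in structures.items():
            converted[name] = mask_to_structure_set(mask).structures.get(mask.label or name, [])
        sset = StructureSet(structures=converted)
    else:
        sset = structures
    if not sset.structures:
        raise ValueError("refusing to write an RT-STRUCT with no structures")

    ct_dsets = _read_series_datasets(ct_dir)
    first = ct_dsets[0]
    z_to_sop = {
        round(float(d.ImagePositionPatient[2]), 4): str(d.SOPInstanceUID) for d in ct_dsets
    }

    ds = Dataset()
    ds.file_meta = FileMetaDataset()
    ds.file_meta.MediaStorageSOPClassUID = RTSTRUCT_STORAGE
    ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
    ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.SOPClassUID = RTSTRUCT_STORAGE
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.PatientName = first.PatientName
    ds.PatientID = first.PatientID
    ds.StudyInstanceUID = first.StudyInstanceUID
    ds.SeriesInstanceUID = generate_uid()
    ds.StructureSetLabel = "contourkit"

    ref_frame = Dataset()
    ref_frame.FrameOfReferenceUID = first.FrameOfReferenceUID
    ds.ReferencedFrameOfReferenceSequence = [ref_frame]

    roi_seq = []
    contour_seq = []
    obs_seq = []
    for number, (name, polys) in enumerate(sset.structures.items(), start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = first.FrameOfReferenceUID
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        roi_seq.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = number
        contours = []
        for z, poly in polys:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            pts = np.column_stack([poly, np.full(len(poly), z)])
            c.NumberOfContourPoints = len(poly)
            c.ContourData = [float(v) for v in pts.ravel()]
            sop = z_to_sop.get(round(float(z), 4))
            if sop is not None:
                img = Dataset()
                img.ReferencedSOPClassUID = CT_STORAGE
                img.ReferencedSOPInstanceUID = sop
                c.ContourImageSequence = [img]
            contours.append(c)
        rc.ContourSequence = contours
        contour_seq.append(rc)

        obs = Dataset()
        obs.ObservationNumber = number
        obs.ReferencedROINumber = number
        obs.RTROIInterpretedType = ""
        obs.ROIInterpreter = ""
        obs_seq.append(obs)

    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.RTROIObservationsSequence = obs_seq
    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# Rasterization / contour extraction
# ---------------------------------------------------------------------------

def _even_odd_fill(xc: np.ndarray, yc: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd point-in-polygon over a grid of voxel centres.

    Crossing-number ray cast toward +x: a centre is inside when the ray
    crosses an odd number of edges.  Centres on lower-x / lower-y edges are
    inside; upper edges are outside (fixed half-open convention).
    """
    X = xc[:, None]
    Y = yc[None, :]
    inside = np.zeros((xc.size, yc.size), dtype=bool)
    x0, y0 = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    for i in range(len(poly)):
        dy = y1[i] - y0[i]
        if dy == 0:
            continue
        crosses = (y0[i] > Y) != (y1[i] > Y)
        x_int = x0[i] + (Y - y0[i]) * (x1[i] - x0[i]) / dy
        inside ^= crosses & (X < x_int)
    return inside


def rasterize(
    structure_set: StructureSet,
    structure: str,
    grid: VoxelGrid,
    source: str = "",
) -> BinaryMask:
    """Rasterize one structure's planar polygons to a binary mask on ``grid``.

    Per slice, each polygon is filled by the even-odd rule over voxel
    centres; multiple polygons on one slice combine by parity (holes
    subtract).  A polygon whose z matches no slice centre within sz/2 is
    dropped with a warning.
    """
    if structure not in structure_set.structures:
        raise KeyError(
            f"structure {structure!r} not in structure set "
            f"(available: {structure_set.names})"
        )
    occ = np.zeros(grid.shape, dtype=bool)
    xc = grid.axis_centers(0)
    yc = grid.axis_centers(1)
    sz = grid.spacing[2]
    for z, poly in structure_set.structures[structure]:
        k = int(np.floor((z - grid.origin[2]) / sz + 0.5))
        if k < 0 or k >= grid.shape[2] or abs(z - (grid.origin[2] + k * sz)) > sz / 2 + 1e-9:
            logger.warning(
                "structure %r: polygon at z=%.3f mm matches no slice; dropped", structure, z
            )
            continue
        occ[:, :, k] ^= _even_odd_fill(xc, yc, np.asarray(poly, dtype=float))
    return BinaryMask(grid, occ, label=structure, source=source)


def mask_to_structure_set(mask: BinaryMask) -> StructureSet:
    """Extract per-slice closed contours (marching squares at 0.5) from a mask."""
    grid = mask.grid
    polys: list[tuple[float, np.ndarray]] = []
    for k in range(grid.shape[2]):
        sl = mask.occupancy[:, :, k]
        if not sl.any():
            continue
        padded = np.pad(sl.astype(float), 1)
        for contour in measure.find_contours(padded, 0.5):
            pts = contour - 1.0  # undo pad
            if np.allclose(pts[0], pts[-1]):
                pts = pts[:-1]
            if len(pts) < 3:
                continue
            xy = np.column_stack(
                [
                    grid.origin[0] + pts[:, 0] * grid.spacing[0],
                    grid.origin[1] + pts[:, 1] * grid.spacing[1],
                ]
            )
            polys.append((grid.origin[2] + k * grid.spacing[2], xy))
    name = mask.label or "structure"
    return StructureSet(structures={name: polys})


# ---------------------------------------------------------------------------
# Case manifest
# ---------------------------------------------------------------------------

def read_manifest(path, check_paths: bool = True) -> pd.DataFrame:
    """Read and validate a case manifest CSV (case, structure, role, path, format).

    Relative paths are resolved against the manifest's directory.  Duplicate
    (case, structure, role) rows and missing referenced files are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest {path} is missing column(s): {', '.join(missing)}")
    bad_fmt = set(df["format"]) - {"nifti", "rtstruct"}
    if bad_fmt:
        raise ManifestError(f"manifest {path}: unknown format(s) {sorted(bad_fmt)}")
    dup = df.duplicated(subset=["case", "structure", "role"])
    if dup.any():
        rows = df.loc[dup, ["case", "structure", "role"]].to_records(index=False).tolist()
        raise ManifestError(f"manifest {path}: duplicate (case, structure, role) rows {rows}")
    base = path.parent
    resolved = [str(p) if Path(p).is_absolute() else str(base / p) for p in df["path"]]
    df = df.assign(path=resolved)
    if check_paths:
        absent = [p for p in df["path"] if not Path(p).exists()]
        if absent:
            raise ManifestError(f"manifest {path}: missing file(s) {absent[:5]}")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=list(MANIFEST_COLUMNS))
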