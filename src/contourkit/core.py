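"""Geometry-aware containers for CT volumes and binary structure masks.

Everything downstream (metrics, consensus statistics, fusion) assumes its
inputs live on a single voxel grid.  The containers here make that contract
explicit: a :class:`VoxelGrid` carries shape, anisotropic spacing (mm) and
origin (mm), and two grids are *compatible* only if all three agree to
within ``GRID_TOL``.  Mismatches are hard errors — callers must resample
explicitly (:func:`resample_mask`) before comparing masks, so no metric is
ever computed across silently misaligned grids.

Conventions
-----------
* Arrays are indexed ``(x, y, z)`` with ``z`` the slice axis.
* Voxel indices are 0-based; the centre of voxel ``(i, j, k)`` sits at
  ``origin + index * spacing`` in patient coordinates (LPS when the data
  came from DICOM).
* Only axis-aligned orientations are supported; oblique direction cosines
  are rejected at I/O time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

GRID_TOL = 1e-6  # mm agreement required for two grids to be "the same"


class GridError(ValueError):
    """Invalid grid geometry (non-positive spacing, empty shape, ...)."""


class AlignmentError(GridError):
    """Operation attempted across incompatible voxel grids."""


def _triple(values: Sequence, kind: type) -> tuple:
    t = tuple(kind(v) for v in values)
    if len(t) != 3:
        raise GridError(f"expected a length-3 sequence, got {values!r}")
    return t


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice: shape (nx, ny, nz), spacing and origin in mm."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", _triple(self.shape, int))
        object.__setattr__(self, "spacing", _triple(self.spacing, float))
        object.__setattr__(self, "origin", _triple(self.origin, float))
        if any(n < 1 for n in self.shape):
            raise GridError(f"all shape components must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise GridError(f"all spacing components must be > 0, got {self.spacing}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def axis_centers(self, axis: int) -> np.ndarray:
        """Physical (mm) coordinates of voxel centres along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def compatible(self, other: "VoxelGrid", tol: float = GRID_TOL) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )

    def require_compatible(self, other: "VoxelGrid") -> None:
        if not self.compatible(other):
            raise AlignmentError(
                f"grids differ (self={self}, other={other}); resample explicitly first"
            )


@dataclass
class ImageVolume:
    """Scalar (Hounsfield-unit-like) volume on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.shape != self.grid.shape:
            raise GridError(
                f"intensity array shape {self.intensities.shape} != grid shape {self.grid.shape}"
            )


@dataclass
class BinaryMask:
    """One structure from one source (observer / model) on a voxel grid."""

    grid: VoxelGrid
    occupancy: np.ndarray
    label: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.shape != self.grid.shape:
            raise GridError(
                f"occupancy shape {self.occupancy.shape} != grid shape {self.grid.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.grid.voxel_volume

    @property
    def empty(self) -> bool:
        return not self.occupancy.any()

    def replace(self, **changes) -> "BinaryMask":
        return dataclasses.replace(self, **changes)


@dataclass
class StructureSet:
    """Planar-contour representation of structures (RT-STRUCT style).

    ``structures`` maps a structure name to a list of ``(z, polygon)`` pairs,
    where ``polygon`` is an ``(n, 2)`` array of in-plane (x, y) vertices in mm
    and ``z`` is the slice position in mm.  Polygons are closed implicitly
    (last vertex connects back to the first) and must have >= 3 vertices.
    """

    frame_of_reference: str = ""
    structures: dict[str, list[tuple[float, np.ndarray]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, polys in self.structures.items():
            for z, poly in polys:
                poly = np.asarray(poly, dtype=float)
                if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                    raise ValueError(
                        f"structure {name!r}: polygons need >= 3 (x, y) vertices"
                    )

    @property
    def names(self) -> list[str]:
        return list(self.structures)


def resample_mask(mask: BinaryMask, target: VoxelGrid) -> BinaryMask:
    """Nearest-neighbour resampling of a binary mask onto ``target``.

    Each target voxel takes the occupancy of the source voxel whose centre is
    nearest to the target voxel centre (per-axis rounding, half rounds up);
    target voxels whose centre falls outside the source extent are False.
    Masks stay strictly binary — no partial-volume fractions.
    """
    if mask.grid.compatible(target):
        return BinaryMask(target, mask.occupancy.copy(), mask.label, mask.source)

    src = mask.grid
    index_per_axis = []
    valid_per_axis = []
    for axis in range(3):
        centers = target.axis_centers(axis)
        # nearest source index, half-way ties round toward +infinity
        idx = np.floor((centers - src.origin[axis]) / src.spacing[axis] + 0.5).astype(int)
        valid = (idx >= 0) & (idx < src.shape[axis])
        index_per_axis.append(np.clip(idx, 0, src.shape[axis] - 1))
        valid_per_axis.append(valid)

    ix, iy, iz = index_per_axis
    occ = mask.occupancy[np.ix_(ix, iy, iz)]
    vx, vy, vz = valid_per_axis
    occ &= vx[:, None, None] & vy[None, :, None] & vz[None, None, :]
    return BinaryMask(target, occ, mask.label, mask.source)


def _check_family(masks: Sequence[BinaryMask], min_count: int = 1) -> None:
    if len(masks) < min_count:
        raise ValueError(f"need at least {min_count} masks, got {len(masks)}")
    first = masks[0]
    for m in masks[1:]:
        first.grid.require_compatible(m.grid)
        if m.label != first.label:
            raise ValueError(
                f"masks belong to different structures: {first.label!r} vs {m.label!r}"
            )


def mask_logic(
    masks: Sequence[BinaryMask],
    op: Literal["intersection", "union", "sum"],
):
    """Voxel-wise combination of compatible masks of one structure.

    ``intersection`` / ``union`` return a :class:`BinaryMask`; ``sum`` returns
    an integer vote-count array in ``[0, M]`` (the ``k_i`` of the kappa and
    fused-agreement formulas).
    """
    _check_family(masks, min_count=1)
    stack = np.stack([m.occupancy for m in masks])
    grid = masks[0].grid
    label = masks[0].label
    if op == "intersection":
        return BinaryMask(grid, stack.all(axis=0), label, "intersection")
    if op == "union":
        return BinaryMask(grid, stack.any(axis=0), label, "union")
    if op == "sum":
        return stack.sum(axis=0, dtype=np.int32)
    raise ValueError(f"unknown op {op!r}")
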