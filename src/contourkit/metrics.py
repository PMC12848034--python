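"""Geometric agreement metrics between a test contour and a reference contour.

The four metrics routinely reported for auto-contouring evaluation:

* DSC — Dice similarity coefficient, ``2|A∩B| / (|A|+|B|)``, overlap in [0, 1].
* RVD — relative volume difference, ``|V_test − V_ref| / V_ref × 100`` (%).
  Unsigned; values above 100% are legal (a contour several times the
  reference volume is a real failure mode for small glands).
* HD95 — 95th-percentile Hausdorff distance (mm) between boundary voxel
  centres, robust to single outlier points.
* ASSD — average symmetric surface distance (mm), the pooled mean of both
  directed nearest-surface distance sets.

Surfaces are voxel based: the boundary of a mask is the mask minus its
6-connected erosion, and directed distances are exact Euclidean distances
between boundary voxel *centres* with anisotropic spacing respected.
Mesh-based surface extraction is deliberately out of scope — voxel surfaces
are deterministic and directly checkable against a brute-force oracle.

Empty-mask policy: when exactly one mask is empty DSC is 0 and the distance
metrics are undefined (NaN, flagged); when both are empty all four metrics
are undefined.  Undefined values are never silently converted to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import BinaryMask

__all__ = [
    "MetricResult",
    "SurfaceDistanceSet",
    "dice",
    "jaccard",
    "relative_volume_difference",
    "surface_distances",
    "hd95",
    "assd",
    "evaluate_pair",
]

_CONN6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class SurfaceDistanceSet:
    """Directed boundary-to-boundary distance lists for one mask pair (mm)."""

    test_to_ref: np.ndarray
    ref_to_test: np.ndarray
    spacing: tuple[float, float, float]


@dataclass(frozen=True)
class MetricResult:
    """The four-metric bundle for one (test, reference) structure pair.

    Undefined metrics are NaN; ``flags`` records why (``empty-test`` /
    ``empty-reference``).
    """

    structure: str
    source: str
    dsc: float
    rvd: float
    hd95: float
    assd: float
    flags: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict:
        return {
            "structure": self.structure,
            "source": self.source,
            "dsc": self.dsc,
            "rvd_pct": self.rvd,
            "hd95_mm": self.hd95,
            "assd_mm": self.assd,
            "flags": ";".join(sorted(self.flags)),
        }


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient; NaN if both masks are empty."""
    a.grid.require_compatible(b.grid)
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 and nb == 0:
        return float("nan")
    inter = int((a.occupancy & b.occupancy).sum())
    return 2.0 * inter / (na + nb)


def jaccard(a: BinaryMask, b: BinaryMask) -> float:
    a.grid.require_compatible(b.grid)
    union = int((a.occupancy | b.occupancy).sum())
    if union == 0:
        return float("nan")
    inter = int((a.occupancy & b.occupancy).sum())
    return inter / union


def relative_volume_difference(test: BinaryMask, ref: BinaryMask) -> float:
    """Unsigned relative volume difference in percent; NaN if ref is empty."""
    test.grid.require_compatible(ref.grid)
    v_ref = ref.volume_mm3
    if v_ref == 0:
        return float("nan")
    return abs(test.volume_mm3 - v_ref) / v_ref * 100.0


def boundary_voxels(mask: BinaryMask) -> np.ndarray:
    """Boolean array marking the boundary: mask minus its 6-connected erosion.

    Voxels on the array edge count as boundary (the volume outside the grid
    is background).
    """
    occ = mask.occupancy
    eroded = ndimage.binary_erosion(occ, structure=_CONN6, border_value=0)
    return occ & ~eroded


def _boundary_points_mm(mask: BinaryMask) -> np.ndarray:
    idx = np.argwhere(boundary_voxels(mask))
    return idx * np.asarray(mask.grid.spacing)


def surface_distances(a: BinaryMask, b: BinaryMask) -> SurfaceDistanceSet:
    """Exact directed nearest-boundary distances between two non-empty masks."""
    a.grid.require_compatible(b.grid)
    if a.empty or b.empty:
        raise ValueError("surface distances are undefined for empty masks")
    pts_a = _boundary_points_mm(a)
    pts_b = _boundary_points_mm(b)
    d_ab, _ = cKDTree(pts_b).query(pts_a)
    d_ba, _ = cKDTree(pts_a).query(pts_b)
    return SurfaceDistanceSet(
        np.asarray(d_ab, dtype=float), np.asarray(d_ba, dtype=float), a.grid.spacing
    )


def hd95(
    sd: SurfaceDistanceSet, mode: Literal["max", "pooled"] = "max"
) -> float:
    """95th-percentile Hausdorff distance (mm).

    ``mode='max'`` (default): max of the two directed 95th percentiles.
    ``mode='pooled'``: 95th percentile of the pooled distance list.
    Percentiles use linear interpolation between order statistics.
    """
    if sd.test_to_ref.size == 0 or sd.ref_to_test.size == 0:
        return float("nan")
    if mode == "max":
        return float(
            max(
                np.percentile(sd.test_to_ref, 95),
                np.percentile(sd.ref_to_test, 95),
            )
        )
    if mode == "pooled":
        return float(np.percentile(np.concatenate([sd.test_to_ref, sd.ref_to_test]), 95))
    raise ValueError(f"unknown hd95 mode {mode!r}")


def assd(sd: SurfaceDistanceSet) -> float:
    """Average symmetric surface distance: pooled mean of both directed lists."""
    n = sd.test_to_ref.size + sd.ref_to_test.size
    if n == 0:
        return float("nan")
    return float((sd.test_to_ref.sum() + sd.ref_to_test.sum()) / n)


def evaluate_pair(
    test: BinaryMask,
    ref: BinaryMask,
    hd95_mode: Literal["max", "pooled"] = "max",
) -> MetricResult:
    """All four metrics for one (test, reference) pair, with empty-mask flags."""
    test.grid.require_compatible(ref.grid)
    flags: set[str] = set()
    if test.empty:
        flags.add("empty-test")
    if ref.empty:
        flags.add("empty-reference")

    if test.empty and ref.empty:
        d = r = h = s = float("nan")
    elif test.empty or ref.empty:
        d = 0.0
        r = relative_volume_difference(test, ref)  # NaN when ref empty, 100% when test empty
        h = s = float("nan")
    else:
        d = dice(test, ref)
        r = relative_volume_difference(test, ref)
        sd = surface_distances(test, ref)
        h = hd95(sd, mode=hd95_mode)
        s = assd(sd)

    return MetricResult(
        structure=ref.label or test.label,
        source=test.source,
        dsc=d,
        rvd=r,
        hd95=h,
        assd=s,
        flags=frozenset(flags),
    )
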