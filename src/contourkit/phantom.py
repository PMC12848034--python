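"""Synthetic CT-like phantoms with known truth structures and simulated observers.

No patient data ship with this package.  Every metric, consensus statistic
and fusion stage is instead exercised on phantoms: a CT-like volume built
from analytic shape recipes (spheres, ellipsoids, tubes, boxes placed at
known HU), and M "model outputs" per structure produced by perturbing the
analytic truth mask with a controllable three-stage pipeline:

1. a seeded rigid shift (Gaussian per axis in mm, rounded to whole voxels),
2. a signed morphological dilation/erosion of random radius,
3. seeded random flips of voxels within one voxel of the boundary.

Severity presets (``none`` / ``low`` / ``medium`` / ``high``) bundle the
three parameters; ``none`` is the identity.  All randomness flows from one
root seed through fixed per-case / per-observer substreams, so adding an
observer never changes existing ones and every output is bit-reproducible.

The default structure menu mirrors the organ classes whose agreement
behaviour differs most in practice: small low-contrast bodies (lens- and
pituitary-like spheres of a few mm) and large high-contrast bodies
(mandible-like bone, parotid-like soft tissue).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .core import BinaryMask, ImageVolume, VoxelGrid

__all__ = [
    "StructureRecipe",
    "PhantomSpec",
    "PerturbationSpec",
    "SEVERITY_PRESETS",
    "default_phantom_spec",
    "derive_seed",
    "make_phantom",
    "perturb_mask",
    "generate_observer_set",
]


def derive_seed(root: int, *keys: int) -> int:
    """Deterministic sub-seed (< 2^31) from a root seed and integer keys.

    Used to give each case / structure / stage its own independent stream so
    that adding cases or observers never perturbs existing ones.
    """
    return int(np.random.SeedSequence([int(root), *map(int, keys)]).generate_state(1)[0] % (2**31))

_CONN6 = ndimage.generate_binary_structure(3, 1)

Shape = Literal["sphere", "ellipsoid", "tube", "box"]


@dataclass(frozen=True)
class StructureRecipe:
    """One analytic structure: shape, centre (mm), radii (mm), intensity (HU)."""

    name: str
    shape: Shape
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    intensity_hu: float

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError(f"structure {self.name!r}: radii must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    grid: VoxelGrid = VoxelGrid((64, 64, 48), (1.0, 1.0, 3.0))
    structures: tuple[StructureRecipe, ...] = ()
    background_hu: float = 0.0
    noise_sd_hu: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_hu < 0:
            raise ValueError("noise SD must be >= 0")


#: severity -> (rigid shift SD mm, signed morph radius bound voxels, boundary flip rate)
SEVERITY_PRESETS: dict[str, tuple[float, int, float]] = {
    "none": (0.0, 0, 0.0),
    "low": (0.5, 1, 0.02),
    "medium": (1.0, 1, 0.05),
    "high": (2.0, 2, 0.10),
}


@dataclass(frozen=True)
class PerturbationSpec:
    """Parameters of the three-stage mask perturbation."""

    shift_sd_mm: float = 1.0
    morph_radius: int = 1  # radius drawn uniformly from [-morph_radius, +morph_radius]
    flip_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.flip_rate < 0.5:
            raise ValueError("flip rate must lie in [0, 0.5)")
        if self.shift_sd_mm < 0 or self.morph_radius < 0:
            raise ValueError("shift SD and morph radius must be >= 0")

    @classmethod
    def from_severity(cls, severity: str, seed: int = 0) -> "PerturbationSpec":
        try:
            shift, morph, flip = SEVERITY_PRESETS[severity]
        except KeyError:
            raise ValueError(
                f"unknown severity {severity!r}; choose from {sorted(SEVERITY_PRESETS)}"
            ) from None
        return cls(shift_sd_mm=shift, morph_radius=morph, flip_rate=flip, seed=seed)

    @property
    def is_identity(self) -> bool:
        return self.shift_sd_mm == 0 and self.morph_radius == 0 and self.flip_rate == 0


def default_phantom_spec(seed: int = 0) -> PhantomSpec:
    """Four disjoint structures spanning the easy-to-hard agreement spectrum.

    HU contrasts: bone-like +800 over soft tissue for the mandible-like box;
    tens of HU (comparable to the 15 HU noise floor) for the lens- and
    pituitary-like spheres, emulating low CT contrast.
    """
    grid = VoxelGrid((64, 64, 48), (1.0, 1.0, 3.0))
    structures = (
        StructureRecipe("mandible_like", "box", (20.0, 20.0, 36.0), (14.0, 9.0, 9.0), 800.0),
        StructureRecipe("parotid_like", "ellipsoid", (44.0, 40.0, 75.0), (11.0, 9.0, 12.0), 45.0),
        StructureRecipe("lens_like", "sphere", (18.0, 46.0, 102.0), (3.0, 3.0, 3.0), 35.0),
        StructureRecipe("pituitary_like", "sphere", (46.0, 14.0, 108.0), (4.0, 4.0, 4.0), 30.0),
    )
    return PhantomSpec(grid=grid, structures=structures, seed=seed)


def _inside(recipe: StructureRecipe, grid: VoxelGrid) -> np.ndarray:
    """Analytic voxel-centre-inside test for one recipe."""
    axes = [grid.axis_centers(a) - recipe.center_mm[a] for a in range(3)]
    x = axes[0][:, None, None]
    y = axes[1][None, :, None]
    z = axes[2][None, None, :]
    rx, ry, rz = recipe.radii_mm
    if recipe.shape in ("sphere", "ellipsoid"):
        return (x / rx) ** 2 + (y / ry) ** 2 + (z / rz) ** 2 <= 1.0
    if recipe.shape == "tube":  # cylinder along z
        return ((x / rx) ** 2 + (y / ry) ** 2 <= 1.0) & (np.abs(z) <= rz)
    if recipe.shape == "box":
        return (np.abs(x) <= rx) & (np.abs(y) <= ry) & (np.abs(z) <= rz)
    raise ValueError(f"unknown shape {recipe.shape!r}")


def make_phantom(spec: PhantomSpec) -> tuple[ImageVolume, dict[str, BinaryMask]]:
    """Build the CT-like volume and the analytic truth mask per structure.

    Truth masks must be pairwise disjoint (overlapping recipes are an error);
    the CT is background HU, overwritten with each structure's HU, plus
    seeded Gaussian noise.  The same seed reproduces the volume bit-exactly.
    """
    grid = spec.grid
    ct = np.full(grid.shape, float(spec.background_hu))
    occupied = np.zeros(grid.shape, dtype=bool)
    truths: dict[str, BinaryMask] = {}
    for recipe in spec.structures:
        occ = _inside(recipe, grid)
        if (occ & occupied).any():
            raise ValueError(f"structure {recipe.name!r} overlaps a previous structure")
        occupied |= occ
        ct[occ] = recipe.intensity_hu
        truths[recipe.name] = BinaryMask(grid, occ, label=recipe.name, source="truth")
    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng([int(spec.seed), 0])
        ct = ct + rng.normal(0.0, spec.noise_sd_hu, size=grid.shape)
    return ImageVolume(grid, ct), truths


def _boundary_band(occ: np.ndarray, spacing) -> np.ndarray:
    """Voxels within one voxel (physical radius min(spacing)) of the boundary."""
    elem = _morph_element(spacing, 1)
    dil = ndimage.binary_dilation(occ, structure=elem)
    ero = ndimage.binary_erosion(occ, structure=elem, border_value=0)
    return dil & ~ero


def perturb_mask(
    truth: BinaryMask,
    pspec: PerturbationSpec,
    rng: np.random.Generator | None = None,
) -> BinaryMask:
    """Apply shift, signed morphology and boundary flips, in that order."""
    if pspec.is_identity:
        return truth.replace(occupancy=truth.occupancy.copy())
    if rng is None:
        rng = np.random.default_rng([int(pspec.seed), 1])
    occ = truth.occupancy

    # 1. rigid shift, rounded to whole voxels
    if pspec.shift_sd_mm > 0:
        shift_mm = rng.normal(0.0, pspec.shift_sd_mm, size=3)
        shift_vox = np.rint(shift_mm / np.asarray(truth.grid.spacing)).astype(int)
        if np.any(shift_vox):
            occ = _shift(occ, shift_vox)

    # 2. signed dilation / erosion
    if pspec.morph_radius > 0:
        radius = int(rng.integers(-pspec.morph_radius, pspec.morph_radius + 1))
        occ = _signed_morph(occ, radius, truth.grid.spacing)

    # 3. boundary voxel flips
    if pspec.flip_rate > 0:
        band = _boundary_band(occ, truth.grid.spacing)
        flips = band & (rng.random(occ.shape) < pspec.flip_rate)
        occ = occ ^ flips

    return truth.replace(occupancy=occ, source="perturbed")


def _shift(occ: np.ndarray, shift_vox: np.ndarray) -> np.ndarray:
    out = np.zeros_like(occ)
    src = []
    dst = []
    for axis, s in enumerate(shift_vox):
        n = occ.shape[axis]
        s = int(np.clip(s, -n, n))
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = occ[tuple(src)]
    return out


def _morph_element(spacing, radius: int) -> np.ndarray:
    """Structuring element of physical radius ``radius * min(spacing)`` mm.

    Interpreting the morph radius as a physical distance keeps severity
    comparable across anisotropic grids: on a (1, 1, 3) mm grid a 1-voxel
    perturbation stays in-plane instead of adding/removing whole 3 mm
    slices, which would dwarf every other perturbation stage for thin
    structures.  On isotropic grids this is the usual 6-connected ball.
    """
    r_mm = radius * min(spacing) + 1e-9
    ranges = [np.arange(-int(r_mm // s), int(r_mm // s) + 1) for s in spacing]
    dx, dy, dz = np.meshgrid(*ranges, indexing="ij")
    dist = np.sqrt(
        (dx * spacing[0]) ** 2 + (dy * spacing[1]) ** 2 + (dz * spacing[2]) ** 2
    )
    return dist <= r_mm


def _signed_morph(occ: np.ndarray, radius: int, spacing) -> np.ndarray:
    if radius > 0:
        return ndimage.binary_dilation(occ, structure=_morph_element(spacing, radius))
    r = -radius
    while r > 0:
        eroded = ndimage.binary_erosion(
            occ, structure=_morph_element(spacing, r), border_value=0
        )
        if eroded.any():
            return eroded
        r -= 1
    if radius < 0 and occ.any():
        import warnings

        warnings.warn(
            "erosion would empty the mask at every radius; returning a 1-voxel seed",
            RuntimeWarning,
            stacklevel=2,
        )
        seed = np.zeros_like(occ)
        centroid = tuple(np.round(np.mean(np.argwhere(occ), axis=0)).astype(int))
        seed[centroid] = True
        return seed
    return occ


def generate_observer_set(
    truth: BinaryMask,
    m: int,
    pspec: PerturbationSpec,
) -> list[BinaryMask]:
    """M independently perturbed "model outputs" of one truth mask.

    Observer k uses the substream ``default_rng([seed, 1, k])`` so observers
    are mutually independent and adding an observer leaves earlier ones
    untouched.
    """
    if m < 2:
        raise ValueError(f"need at least 2 observers, got {m}")
    observers = []
    for k in range(m):
        rng = np.random.default_rng([int(pspec.seed), 1, k])
        obs = perturb_mask(truth, pspec, rng=rng)
        obs.source = f"model-{k + 1}"
        observers.append(obs)
    return observers
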