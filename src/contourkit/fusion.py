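"""Training-free confidence-based fusion of multiple auto-contouring outputs.

Given M binary masks of one structure from different models plus the planning
CT, fusion proceeds in three steps:

1. **Trimap** — voxels inside the intersection of the masks are definite
   FOREGROUND, voxels outside the union are definite BACKGROUND, and the
   rest (where the models disagree) form the UNCERTAIN region.
2. **Confidence map** — each uncertain voxel receives a confidence
   c in [0, 1] from the CT: c solves the discrete Laplace equation on the
   uncertain voxels with boundary conditions c = 1 on FOREGROUND and c = 0
   on BACKGROUND, with 6-neighbour edge weights
   ``w_uv = exp(−β (I_u − I_v)² / σ_I²)`` (a random-walker-style harmonic
   potential).  Uniform intensities make c pure lattice interpolation; a
   strong intensity edge inside the uncertain band blocks diffusion, so the
   fused boundary snaps to image edges.  No training is involved.
3. **Threshold** — the fused mask is FOREGROUND plus the uncertain voxels
   with c >= t.  Because c is bounded, the result always satisfies
   intersection ⊆ fused ⊆ union, and the fused masks are nested in t.
   The per-structure threshold t is chosen on training cases to maximise
   mean DSC against the reference (:func:`select_threshold`).

For downstream learned fusion, :func:`assemble_channels` stacks the
normalized CT, the fused agreement map (vote fraction k_i / M) and the
confidence map as aligned channels; network training itself is out of scope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from .core import AlignmentError, BinaryMask, ImageVolume, VoxelGrid, mask_logic, _check_family
from .metrics import dice

__all__ = [
    "Trimap",
    "ConfidenceMap",
    "ConfidenceConfig",
    "ThresholdSelection",
    "FusedChannelStack",
    "build_trimap",
    "fused_agreement_map",
    "confidence_map",
    "apply_threshold",
    "select_threshold",
    "fuse",
    "assemble_channels",
    "DEFAULT_THRESHOLD_GRID",
]

logger = logging.getLogger(__name__)

BACKGROUND, UNCERTAIN, FOREGROUND = 0, 1, 2
_CONN6 = ndimage.generate_binary_structure(3, 1)

DEFAULT_THRESHOLD_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))

W_FLOOR = 1e-10  # additive floor on edge affinities; keeps the Laplacian nonsingular


class SolverError(RuntimeError):
    """Harmonic solve failed to reach the requested residual tolerance."""


@dataclass
class Trimap:
    """Three-way partition of the grid: definite foreground / background / uncertain."""

    grid: VoxelGrid
    state: np.ndarray  # uint8, values in {BACKGROUND, UNCERTAIN, FOREGROUND}

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=np.uint8)
        if self.state.shape != self.grid.shape:
            raise ValueError("trimap state shape does not match its grid")
        if self.state.max(initial=0) > FOREGROUND:
            raise ValueError("trimap states must be 0 (bg), 1 (uncertain) or 2 (fg)")

    @property
    def foreground(self) -> np.ndarray:
        return self.state == FOREGROUND

    @property
    def background(self) -> np.ndarray:
        return self.state == BACKGROUND

    @property
    def uncertain(self) -> np.ndarray:
        return self.state == UNCERTAIN


@dataclass
class ConfidenceMap:
    grid: VoxelGrid
    confidence: np.ndarray

    def __post_init__(self) -> None:
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.confidence.shape != self.grid.shape:
            raise ValueError("confidence shape does not match its grid")
        if self.confidence.min() < -1e-9 or self.confidence.max() > 1 + 1e-9:
            raise ValueError("confidence values must lie in [0, 1]")


@dataclass(frozen=True)
class ConfidenceConfig:
    """Parameters of the harmonic confidence solve.

    beta: edge sensitivity (dimensionless, >= 0).  0 ignores the CT entirely.
    sigma: intensity scale in HU; None -> robust SD (1.4826·MAD) of the CT
        inside the union bounding box.
    tol: max allowed residual of the linear solve (infinity norm).
    max_iter: iteration cap for the iterative fallback solver.
    method: 'harmonic' (direct sparse solve) or 'distance_ratio'
        (c = d_BG / (d_FG + d_BG) with Euclidean distance transforms — a
        cheap geometric fallback for very large uncertain regions; it ignores
        the CT).
    """

    beta: float = 2.0
    sigma: float | None = None
    tol: float = 1e-8
    max_iter: int = 2000
    method: str = "harmonic"

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class ThresholdSelection:
    """Result of the training-set grid search over confidence thresholds."""

    structure: str
    threshold: float
    grid: tuple[float, ...]
    mean_dsc: tuple[float, ...]
    n_cases: int


@dataclass
class FusedChannelStack:
    """Aligned input channels for a learned fusion network: CT, agreement, confidence."""

    grid: VoxelGrid
    ct: np.ndarray
    agreement: np.ndarray
    confidence: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ct", "agreement", "confidence"):
            arr = np.asarray(getattr(self, name), dtype=np.float32)
            if arr.shape != self.grid.shape:
                raise AlignmentError(f"channel {name!r} is not on the shared grid")
            setattr(self, name, arr)

    def as_array(self) -> np.ndarray:
        """(3, nx, ny, nz) float32 stack in channel order ct, agreement, confidence."""
        return np.stack([self.ct, self.agreement, self.confidence])


def build_trimap(masks: Sequence[BinaryMask]) -> Trimap:
    """Intersection -> FOREGROUND, union complement -> BACKGROUND, rest UNCERTAIN."""
    _check_family(masks, min_count=2)
    inter = mask_logic(list(masks), "intersection").occupancy
    union = mask_logic(list(masks), "union").occupancy
    state = np.zeros(masks[0].grid.shape, dtype=np.uint8)
    state[union] = UNCERTAIN
    state[inter] = FOREGROUND
    if not union.any():
        logger.warning("all input masks empty: degenerate all-background trimap")
    return Trimap(masks[0].grid, state)


def fused_agreement_map(masks: Sequence[BinaryMask]) -> np.ndarray:
    """Per-voxel vote fraction k_i / M in {0, 1/M, ..., 1}."""
    _check_family(masks, min_count=2)
    counts = mask_logic(list(masks), "sum")
    return counts.astype(float) / len(masks)


def _robust_sigma(ct: ImageVolume, trimap: Trimap) -> float:
    """Robust intensity SD (1.4826·MAD) inside the union bounding box."""
    union = trimap.state > BACKGROUND
    if union.any():
        idx = np.argwhere(union)
        lo, hi = idx.min(axis=0), idx.max(axis=0)
        patch = ct.intensities[lo[0]: hi[0] + 1, lo[1]: hi[1] + 1, lo[2]: hi[2] + 1]
    else:
        patch = ct.intensities
    med = np.median(patch)
    sigma = 1.4826 * float(np.median(np.abs(patch - med)))
    if sigma <= 1e-9:
        sigma = float(np.std(patch))
    return max(sigma, 1e-6)


def _solve_harmonic(
    intens: np.ndarray,
    state: np.ndarray,
    beta: float,
    sigma: float,
    tol: float,
) -> np.ndarray:
    """Solve the weighted Laplace equation on UNCERTAIN voxels.

    Seeded (FOREGROUND/BACKGROUND) voxels are Dirichlet boundary values 1/0.
    Uncertain components not connected to any seed default to confidence 0
    (no path to foreground); components touching only foreground get 1,
    only background get 0.
    """
    conf = np.zeros(state.shape, dtype=float)
    conf[state == FOREGROUND] = 1.0
    uncertain = state == UNCERTAIN
    if not uncertain.any():
        return conf

    fg_adjacent = ndimage.binary_dilation(state == FOREGROUND, structure=_CONN6) & uncertain
    bg_adjacent = ndimage.binary_dilation(state == BACKGROUND, structure=_CONN6) & uncertain
    labels, n_comp = ndimage.label(uncertain, structure=_CONN6)
    touches_fg = np.zeros(n_comp + 1, dtype=bool)
    touches_bg = np.zeros(n_comp + 1, dtype=bool)
    touches_fg[np.unique(labels[fg_adjacent])] = True
    touches_bg[np.unique(labels[bg_adjacent])] = True
    # components at the grid border see implicit background outside the grid
    border = np.zeros(state.shape, dtype=bool)
    border[[0, -1], :, :] = border[:, [0, -1], :] = border[:, :, [0, -1]] = True
    touches_bg[np.unique(labels[uncertain & border])] = True

    solve_comp = touches_fg & touches_bg
    solve_comp[0] = False
    only_fg = touches_fg & ~touches_bg
    only_fg[0] = False
    conf[only_fg[labels] & uncertain] = 1.0
    # only-background / isolated components stay at 0

    unknown = solve_comp[labels] & uncertain
    n_unknown = int(unknown.sum())
    if n_unknown == 0:
        return conf

    index = -np.ones(state.shape, dtype=np.int64)
    index[unknown] = np.arange(n_unknown)

    inv_sigma2 = 1.0 / (sigma * sigma)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    diag = np.zeros(n_unknown, dtype=float)
    rhs = np.zeros(n_unknown, dtype=float)

    def _shifted(arr, axis, step):
        out = np.empty_like(arr)
        sl_src = [slice(None)] * 3
        sl_dst = [slice(None)] * 3
        if step == 1:
            sl_src[axis] = slice(1, None)
            sl_dst[axis] = slice(0, -1)
        else:
            sl_src[axis] = slice(0, -1)
            sl_dst[axis] = slice(1, None)
        out[tuple(sl_dst)] = arr[tuple(sl_src)]
        # out-of-grid neighbours marked invalid by caller via the pad slice
        return out, tuple(sl_dst)

    for axis in range(3):
        for step in (1, -1):
            nb_state, valid_sl = _shifted(state, axis, step)
            nb_index, _ = _shifted(index, axis, step)
            nb_intens, _ = _shifted(intens, axis, step)
            valid = np.zeros(state.shape, dtype=bool)
            valid[valid_sl] = True
            here = unknown & valid
            if not here.any():
                continue
            u = index[here]
            # floor keeps the system nonsingular when strong edges underflow exp()
            w = np.exp(-beta * (intens[here] - nb_intens[here]) ** 2 * inv_sigma2) + W_FLOOR
            nbs = nb_state[here]
            nbi = nb_index[here]
            # every in-grid neighbour contributes its weight to the diagonal
            np.add.at(diag, u, w)
            fg_nb = nbs == FOREGROUND
            np.add.at(rhs, u[fg_nb], w[fg_nb])
            unk_nb = nbi >= 0
            rows.append(u[unk_nb])
            cols.append(nbi[unk_nb])
            vals.append(-w[unk_nb])

    rows.append(np.arange(n_unknown))
    cols.append(np.arange(n_unknown))
    vals.append(diag)
    a = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_unknown, n_unknown),
    ).tocsr()
    x = spsolve(a, rhs)
    residual = float(np.abs(a @ x - rhs).max())
    if not np.isfinite(x).all() or residual > max(tol, tol * np.abs(rhs).max()):
        raise SolverError(f"harmonic solve residual {residual:.3e} exceeds tolerance {tol:.1e}")
    conf[unknown] = np.clip(x, 0.0, 1.0)
    return conf


def _distance_ratio(state: np.ndarray, spacing) -> np.ndarray:
    """Geometric fallback: c = d_BG / (d_FG + d_BG) with Euclidean distances."""
    conf = np.zeros(state.shape, dtype=float)
    conf[state == FOREGROUND] = 1.0
    uncertain = state == UNCERTAIN
    if not uncertain.any():
        return conf
    d_fg = ndimage.distance_transform_edt(state != FOREGROUND, sampling=spacing)
    d_bg = ndimage.distance_transform_edt(state != BACKGROUND, sampling=spacing)
    denom = d_fg + d_bg
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, d_bg / denom, 0.0)
    if not (state == FOREGROUND).any():
        c = np.zeros_like(c)
    elif not (state == BACKGROUND).any():
        c = np.ones_like(c)
    conf[uncertain] = np.clip(c[uncertain], 0.0, 1.0)
    return conf


def confidence_map(
    ct: ImageVolume,
    trimap: Trimap,
    cfg: ConfidenceConfig = ConfidenceConfig(),
) -> ConfidenceMap:
    """Per-voxel confidence in [0, 1]: 1 on foreground, 0 on background,
    harmonic CT-driven interpolation on the uncertain region."""
    ct.grid.require_compatible(trimap.grid)
    if cfg.method == "distance_ratio":
        conf = _distance_ratio(trimap.state, trimap.grid.spacing)
    elif cfg.method == "harmonic":
        sigma = cfg.sigma if cfg.sigma is not None else _robust_sigma(ct, trimap)
        conf = _solve_harmonic(
            np.asarray(ct.intensities, dtype=float), trimap.state, cfg.beta, sigma, cfg.tol
        )
    else:
        raise ValueError(f"unknown confidence method {cfg.method!r}")
    return ConfidenceMap(trimap.grid, conf)


def apply_threshold(trimap: Trimap, confidence: ConfidenceMap, t: float) -> BinaryMask:
    """Fused mask = FOREGROUND plus uncertain voxels with confidence >= t.

    The comparison allows a 1e-9 slack so voxels whose exact harmonic value
    equals t (e.g. the midpoint of a symmetric uncertain band) are included
    regardless of solver roundoff.
    """
    if not 0.0 < t < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {t}")
    trimap.grid.require_compatible(confidence.grid)
    occ = trimap.foreground | (trimap.uncertain & (confidence.confidence >= t - 1e-9))
    return BinaryMask(trimap.grid, occ, source="fused")


def select_threshold(
    training_cases: Sequence[tuple[ImageVolume, Sequence[BinaryMask], BinaryMask]],
    structure: str = "",
    grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    cfg: ConfidenceConfig = ConfidenceConfig(),
) -> ThresholdSelection:
    """Grid search for the confidence threshold maximising mean training DSC.

    Each training case is ``(ct, model_masks, reference)``.  The confidence
    map is computed once per case; every candidate threshold is then scored
    by DSC against the reference and averaged over cases (cases where DSC is
    undefined are skipped per candidate).  Ties are broken toward the
    candidate nearest 0.5, then the smaller.
    """
    if not training_cases:
        raise ValueError("need at least one training case")
    grid = tuple(float(t) for t in grid)
    if any(not 0 < t < 1 for t in grid):
        raise ValueError("all threshold candidates must lie in (0, 1)")

    scores = np.full((len(training_cases), len(grid)), np.nan)
    for i, (ct, masks, reference) in enumerate(training_cases):
        tm = build_trimap(list(masks))
        cm = confidence_map(ct, tm, cfg)
        for j, t in enumerate(grid):
            scores[i, j] = dice(apply_threshold(tm, cm, t), reference)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_dsc = np.nanmean(scores, axis=0)
    if np.isnan(mean_dsc).all():
        raise ValueError("threshold selection failed: DSC undefined on every training case")

    best = np.nanmax(mean_dsc)
    tied = [t for t, s in zip(grid, mean_dsc) if s >= best - 1e-12]
    t_star = min(tied, key=lambda t: (abs(t - 0.5), t))
    return ThresholdSelection(
        structure=structure,
        threshold=float(t_star),
        grid=grid,
        mean_dsc=tuple(float(s) for s in mean_dsc),
        n_cases=len(training_cases),
    )


def fuse(
    ct: ImageVolume,
    masks: Sequence[BinaryMask],
    threshold: float | ThresholdSelection = 0.5,
    cfg: ConfidenceConfig = ConfidenceConfig(),
) -> BinaryMask:
    """End-to-end training-free fusion: trimap -> confidence -> threshold."""
    if isinstance(threshold, ThresholdSelection):
        threshold = threshold.threshold
    tm = build_trimap(list(masks))
    cm = confidence_map(ct, tm, cfg)
    fused = apply_threshold(tm, cm, threshold)
    fused.label = masks[0].label
    return fused


def normalize_ct(
    intensities: np.ndarray, window: tuple[float, float] = (-200.0, 300.0)
) -> np.ndarray:
    """Clip to the HU window then min-max scale to [0, 1].

    The default window targets head-and-neck soft-tissue contrast.  Images
    that are constant after clipping map to all-zero.
    """
    lo, hi = window
    clipped = np.clip(np.asarray(intensities, dtype=float), lo, hi)
    cmin, cmax = clipped.min(), clipped.max()
    if cmax - cmin <= 0:
        return np.zeros_like(clipped)
    return (clipped - cmin) / (cmax - cmin)


def assemble_channels(
    ct: ImageVolume,
    masks: Sequence[BinaryMask],
    confidence: ConfidenceMap,
    window: tuple[float, float] = (-200.0, 300.0),
) -> FusedChannelStack:
    """Stack normalized CT, agreement map and confidence map as aligned channels."""
    _check_family(masks, min_count=2)
    ct.grid.require_compatible(masks[0].grid)
    ct.grid.require_compatible(confidence.grid)
    return FusedChannelStack(
        grid=ct.grid,
        ct=normalize_ct(ct.intensities, window),
        agreement=fused_agreement_map(list(masks)),
        confidence=confidence.confidence,
    )
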