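"""Multi-observer consensus statistics for one structure contoured by M sources.

Implements the consensus analyses commonly run when several auto-contouring
models (or human observers) delineate the same structure:

* per-case volume summaries (min / max / mean / SD, intersection, union);
* voxel-wise overall (Fleiss) kappa with a large-sample z-test of the
  chance-agreement null hypothesis kappa = 0, plus an optional permutation
  test for small regions;
* the generalized conformity index (CI-gen) of Kouwenhoven et al., the
  pair-sum form ``Σ_{i<j} |A_i ∩ A_j| / Σ_{i<j} |A_i ∪ A_j|`` that is not
  limited by the number of observers and equals the Jaccard index for M = 2;
* binary STAPLE (Warfield's EM) estimating a probabilistic consensus map
  together with each rater's sensitivity p_j and specificity q_j.

Voxel-wise kappa depends on how much background enters the contingency
table: counting the whole scan inflates agreement with trivially concordant
background.  All statistics here are therefore computed over an explicit
:class:`AnalysisRegion` — by default the bounding box of the union of all
masks dilated by 10 mm — and the region is recorded in every result.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import BinaryMask, VoxelGrid, mask_logic, _check_family

__all__ = [
    "VolumeSummary",
    "AnalysisRegion",
    "KappaResult",
    "StapleResult",
    "volume_summary",
    "analysis_region",
    "overall_kappa",
    "classify_agreement",
    "ci_gen",
    "staple",
    "consensus_report",
]

logger = logging.getLogger(__name__)

#: kappa bands: 0 none, (0, 0.20] slight, (0.20, 0.40] fair, (0.40, 0.60]
#: moderate, (0.60, 0.80] substantial, (0.80, 1] almost-perfect
AGREEMENT_BANDS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost-perfect"),
)


@dataclass(frozen=True)
class VolumeSummary:
    structure: str
    volumes_mm3: dict[str, float]
    minimum: float
    maximum: float
    mean: float
    sd: float
    intersection_mm3: float
    union_mm3: float


@dataclass
class AnalysisRegion:
    """Voxels entering the kappa / STAPLE contingency tables.

    Built as the bounding box of the union of the observer masks dilated by
    ``margin_mm`` (per axis, in voxels), optionally intersected with a body
    mask.  Always a superset of the union.
    """

    grid: VoxelGrid
    mask: np.ndarray
    margin_mm: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("region mask shape does not match its grid")
        if not self.mask.any():
            raise ValueError("analysis region is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float
    z: float
    p_value: float
    n: int
    m: int
    p_value_permutation: float | None = None


@dataclass
class StapleResult:
    """Binary STAPLE output on an analysis region.

    ``probability`` is the full-grid posterior W_i (0 outside the region);
    ``sensitivity``/``specificity`` are per-rater p_j / q_j in rater order.
    """

    grid: VoxelGrid
    probability: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    prior: float
    iterations: int
    converged: bool
    log_likelihood: list[float] = field(default_factory=list)

    def consensus_mask(self, threshold: float = 0.5, label: str = "", ) -> BinaryMask:
        # ties at the threshold go to foreground
        return BinaryMask(self.grid, self.probability >= threshold, label, "staple")


def volume_summary(masks: Sequence[BinaryMask]) -> VolumeSummary:
    """Per-case volume statistics over >= 2 compatible masks of one structure."""
    _check_family(masks, min_count=2)
    vols = np.array([m.volume_mm3 for m in masks])
    inter = mask_logic(list(masks), "intersection").volume_mm3
    union = mask_logic(list(masks), "union").volume_mm3
    return VolumeSummary(
        structure=masks[0].label,
        volumes_mm3={m.source or f"source-{i}": float(v) for i, (m, v) in enumerate(zip(masks, vols))},
        minimum=float(vols.min()),
        maximum=float(vols.max()),
        mean=float(vols.mean()),
        sd=float(vols.std(ddof=1)),
        intersection_mm3=float(inter),
        union_mm3=float(union),
    )


def analysis_region(
    masks: Sequence[BinaryMask],
    margin_mm: float = 10.0,
    body: BinaryMask | None = None,
) -> AnalysisRegion:
    """Union bounding box dilated by ``margin_mm``, clipped to the grid."""
    _check_family(masks, min_count=1)
    grid = masks[0].grid
    union = mask_logic(list(masks), "union").occupancy
    region = np.zeros(grid.shape, dtype=bool)
    if not union.any():
        # degenerate: no foreground anywhere; fall back to the whole grid
        region[:] = True
    else:
        idx = np.argwhere(union)
        lo = idx.min(axis=0)
        hi = idx.max(axis=0)
        pad = [int(np.ceil(margin_mm / s)) for s in grid.spacing]
        lo = np.maximum(lo - pad, 0)
        hi = np.minimum(hi + pad, np.asarray(grid.shape) - 1)
        region[lo[0]: hi[0] + 1, lo[1]: hi[1] + 1, lo[2]: hi[2] + 1] = True
    if body is not None:
        grid.require_compatible(body.grid)
        region &= body.occupancy | union
    return AnalysisRegion(grid, region, margin_mm)


def _vote_counts(masks: Sequence[BinaryMask], region: AnalysisRegion) -> np.ndarray:
    counts = mask_logic(list(masks), "sum")
    return counts[region.mask]


def fleiss_kappa_from_votes(k: np.ndarray, m: int) -> tuple[float, float, float]:
    """Fleiss' multi-rater kappa for two categories from foreground votes.

    ``k`` holds, per subject (voxel), the number of the ``m`` raters voting
    foreground.  Returns (kappa, observed agreement, expected agreement).
    """
    k = np.asarray(k, dtype=float)
    n = k.size
    p_i = (k * (k - 1) + (m - k) * (m - k - 1)) / (m * (m - 1))
    p_bar = float(p_i.mean())
    p_hat = float(k.sum() / (n * m))
    p_e = p_hat ** 2 + (1.0 - p_hat) ** 2
    if p_e >= 1.0:
        raise ValueError(
            "kappa undefined: every rater gave the same answer at every voxel "
            "(all-empty or all-full region)"
        )
    kappa = (p_bar - p_e) / (1.0 - p_e)
    return kappa, p_bar, p_e


def overall_kappa(
    masks: Sequence[BinaryMask],
    region: AnalysisRegion | None = None,
    margin_mm: float = 10.0,
    permutations: int = 0,
    seed: int | None = None,
) -> KappaResult:
    """Voxel-wise overall (Fleiss) kappa over the analysis region.

    The z statistic uses the Fleiss–Nee–Landis large-sample variance of
    overall kappa under H0 (kappa = 0), which for two categories reduces to
    ``Var0 = 2 / (n·M·(M−1))`` independent of the margins.  The p-value is
    one-sided: agreement exceeding chance.

    ``permutations > 0`` additionally estimates a permutation p-value by
    randomly translating each mask within the region (seeded), for small
    regions where the normal approximation is doubtful.
    """
    _check_family(masks, min_count=2)
    m = len(masks)
    if region is None:
        region = analysis_region(masks, margin_mm=margin_mm)
    else:
        region.grid.require_compatible(masks[0].grid)
    k = _vote_counts(masks, region)
    n = k.size
    kappa, p_bar, p_e = fleiss_kappa_from_votes(k, m)

    var0 = 2.0 / (n * m * (m - 1))
    z = kappa / np.sqrt(var0)
    p = float(stats.norm.sf(z))

    p_perm = None
    if permutations > 0:
        p_perm = _permutation_pvalue(masks, region, kappa, permutations, seed)

    return KappaResult(
        kappa=float(kappa),
        observed_agreement=p_bar,
        expected_agreement=p_e,
        z=float(z),
        p_value=p,
        n=int(n),
        m=m,
        p_value_permutation=p_perm,
    )


def _permutation_pvalue(
    masks: Sequence[BinaryMask],
    region: AnalysisRegion,
    observed: float,
    permutations: int,
    seed: int | None,
) -> float:
    """Null distribution by independent random cyclic translations of each mask."""
    rng = np.random.default_rng(seed)
    m = len(masks)
    shape = np.asarray(masks[0].grid.shape)
    exceed = 0
    for _ in range(permutations):
        shifted = []
        for mask in masks:
            shift = rng.integers(0, shape)
            shifted.append(np.roll(mask.occupancy, tuple(shift), axis=(0, 1, 2)))
        k = np.stack(shifted).sum(axis=0, dtype=np.int32)[region.mask]
        try:
            kp, _, _ = fleiss_kappa_from_votes(k, m)
        except ValueError:
            kp = 1.0  # degenerate all-agree permutation counts against H1
        if kp >= observed:
            exceed += 1
    return (exceed + 1) / (permutations + 1)


def classify_agreement(kappa: float) -> str:
    """Map a kappa value to the conventional agreement band."""
    if kappa > 1:
        raise ValueError(f"kappa must be <= 1, got {kappa}")
    if kappa <= 0:
        return "none"
    for upper, label in AGREEMENT_BANDS:
        if kappa <= upper + 1e-12:
            return label
    return "almost-perfect"


def ci_gen(masks: Sequence[BinaryMask]) -> float:
    """Generalized conformity index (pair-sum form).

    ``Σ_{pairs i<j} |A_i ∩ A_j| / Σ_{pairs i<j} |A_i ∪ A_j|`` — order
    invariant, defined for any number of observers, equal to the Jaccard
    index when M = 2.  NaN when every mask is empty.
    """
    _check_family(masks, min_count=2)
    inter_sum = 0
    union_sum = 0
    for a, b in itertools.combinations(masks, 2):
        inter_sum += int((a.occupancy & b.occupancy).sum())
        union_sum += int((a.occupancy | b.occupancy).sum())
    if union_sum == 0:
        return float("nan")
    return inter_sum / union_sum


def staple(
    masks: Sequence[BinaryMask],
    region: AnalysisRegion | None = None,
    margin_mm: float = 10.0,
    prior: float | None = None,
    init: float = 0.99,
    tol: float = 1e-7,
    max_iter: int = 200,
) -> StapleResult:
    """Binary STAPLE: EM estimation of a consensus probability map.

    E-step, per region voxel i with rater decisions d_ij:
        a_i = f_T  Π_j p_j^d_ij (1−p_j)^(1−d_ij)
        b_i = (1−f_T) Π_j q_j^(1−d_ij) (1−q_j)^d_ij
        W_i = a_i / (a_i + b_i)
    M-step:
        p_j = Σ_i W_i d_ij / Σ_i W_i
        q_j = Σ_i (1−W_i)(1−d_ij) / Σ_i (1−W_i)

    Initialization p_j = q_j = ``init``; spatially uniform foreground prior
    f_T defaulting to the mean foreground fraction across raters within the
    region.  Convergence when ``max_j(|Δp_j| + |Δq_j|) < tol``.  The
    observed-data log-likelihood ``Σ_i log(a_i + b_i)`` is recorded per
    iteration (non-decreasing under EM).
    """
    _check_family(masks, min_count=2)
    if region is None:
        region = analysis_region(masks, margin_mm=margin_mm)
    else:
        region.grid.require_compatible(masks[0].grid)

    d = np.stack([m.occupancy[region.mask] for m in masks]).astype(float)  # (M, n)
    m_raters, n = d.shape

    if prior is None:
        prior = float(d.mean())
    f_t = float(np.clip(prior, 1e-6, 1.0 - 1e-6))

    p = np.full(m_raters, init, dtype=float)
    q = np.full(m_raters, init, dtype=float)

    eps = 1e-10
    ll_trace: list[float] = []
    converged = False
    iterations = 0
    w = np.full(n, f_t)
    for iterations in range(1, max_iter + 1):
        # E-step in log space for numerical safety
        log_a = np.log(f_t) + (
            d.T @ np.log(np.clip(p, eps, 1.0))
            + (1.0 - d.T) @ np.log(np.clip(1.0 - p, eps, 1.0))
        )
        log_b = np.log(1.0 - f_t) + (
            (1.0 - d.T) @ np.log(np.clip(q, eps, 1.0))
            + d.T @ np.log(np.clip(1.0 - q, eps, 1.0))
        )
        hi = np.maximum(log_a, log_b)
        ll_trace.append(float(np.sum(hi + np.log(np.exp(log_a - hi) + np.exp(log_b - hi)))))
        w = 1.0 / (1.0 + np.exp(log_b - log_a))

        # M-step
        sw = w.sum()
        swc = (1.0 - w).sum()
        if sw < eps or swc < eps:
            warnings.warn(
                "STAPLE posterior collapsed to one class; denominators clamped",
                RuntimeWarning,
                stacklevel=2,
            )
        sw = max(sw, eps)
        swc = max(swc, eps)
        p_new = (d * w).sum(axis=1) / sw
        q_new = ((1.0 - d) * (1.0 - w)).sum(axis=1) / swc

        delta = np.abs(p_new - p) + np.abs(q_new - q)
        p, q = p_new, q_new
        if delta.max() < tol:
            converged = True
            break

    prob = np.zeros(region.grid.shape, dtype=float)
    prob[region.mask] = w
    return StapleResult(
        grid=region.grid,
        probability=prob,
        sensitivity=p,
        specificity=q,
        prior=f_t,
        iterations=iterations,
        converged=converged,
        log_likelihood=ll_trace,
    )


def consensus_report(
    masks_by_structure: dict[str, Sequence[BinaryMask]],
    margin_mm: float = 10.0,
    staple_kwargs: dict | None = None,
) -> pd.DataFrame:
    """One-row-per-structure consensus table for a single case.

    Structures with fewer than 2 sources are skipped with a warning.
    Columns cover the volume summary, kappa (+ band, z, p), CI-gen and a
    STAPLE summary (mean sensitivity/specificity, iteration count).
    """
    rows = []
    for structure, masks in masks_by_structure.items():
        masks = list(masks)
        if len(masks) < 2:
            logger.warning(
                "structure %r has %d source(s); skipped from consensus report",
                structure,
                len(masks),
            )
            continue
        vs = volume_summary(masks)
        region = analysis_region(masks, margin_mm=margin_mm)
        kr = overall_kappa(masks, region=region)
        sr = staple(masks, region=region, **(staple_kwargs or {}))
        rows.append(
            {
                "structure": structure,
                "n_sources": len(masks),
                "vol_min_mm3": vs.minimum,
                "vol_max_mm3": vs.maximum,
                "vol_mean_mm3": vs.mean,
                "vol_sd_mm3": vs.sd,
                "vol_intersection_mm3": vs.intersection_mm3,
                "vol_union_mm3": vs.union_mm3,
                "kappa": kr.kappa,
                "kappa_z": kr.z,
                "kappa_p": kr.p_value,
                "agreement": classify_agreement(kr.kappa),
                "ci_gen": ci_gen(masks),
                "region_voxels": region.n_voxels,
                "staple_sensitivity_mean": float(sr.sensitivity.mean()),
                "staple_specificity_mean": float(sr.specificity.mean()),
                "staple_iterations": sr.iterations,
                "staple_converged": sr.converged,
            }
        )
    return pd.DataFrame(rows)


def agreement_long_table(reports: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-case consensus reports into a box-plot-ready long table."""
    frames = []
    for case, df in reports.items():
        if df.empty:
            continue
        sub = df[["structure", "kappa", "ci_gen"]].copy()
        sub.insert(0, "case", case)
        frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=["case", "structure", "kappa", "ci_gen"])
    long = pd.concat(frames, ignore_index=True)
    return long.melt(
        id_vars=["case", "structure"],
        value_vars=["kappa", "ci_gen"],
        var_name="statistic",
        value_name="value",
    )
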