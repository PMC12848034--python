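# Methods

`contourkit` evaluates how consistently several auto-contouring systems (or
human observers) delineate the same radiotherapy structure, and fuses their
binary masks into a single contour without any model training. This note
records the statistical machinery, the numerical choices, and what the
synthetic phantoms do and do not demonstrate.

## Geometry and containers

All computations happen on a shared axis-aligned voxel lattice
(`VoxelGrid`): shape `(nx, ny, nz)`, anisotropic spacing in mm (head-and-neck
planning CTs typically use ~1 mm in-plane and 3 mm slices), origin in
patient coordinates (LPS when sourced from DICOM). The centre of voxel
`(i, j, k)` is `origin + index · spacing`. Two grids count as identical only
when shape, spacing and origin agree within 1e-6 mm; anything else is a hard
`AlignmentError`, never silent re-gridding — a distance or overlap computed
across misaligned grids is meaningless, so the caller must resample
explicitly. Mask resampling is nearest-neighbour on voxel centres (masks
stay strictly binary; partial-volume fractions are deliberately not
produced), with half-way ties rounded up, so resampling is deterministic and
idempotent on the target grid.

RT-STRUCT contour polygons are rasterized per slice by the even-odd
(crossing-number) rule over voxel centres: a centre is inside when a ray
toward +x crosses an odd number of edges; multiple polygons on one slice
combine by parity, so holes subtract. Centres lying exactly on a polygon
edge are resolved by the half-open convention (lower-x / lower-y edges
inside, upper edges outside), making voxel counts deterministic across
platforms. Boundary-voxel counts can therefore differ from other software by
one boundary layer; the convergence of rasterized area to polygon area as
spacing shrinks is what the tests pin down.

## Agreement metrics

For a test mask A and reference mask B on one grid:

* **DSC** = 2|A∩B| / (|A|+|B|), in [0, 1].
* **RVD** = |V_A − V_B| / V_B × 100 (%), volumes in mm³ from the voxel count
  times the voxel volume. Unsigned — published evaluation tables report
  magnitudes — and unbounded above (a small gland contoured several times
  too large legitimately gives RVD > 100%).
* **Surface distances** use voxel surfaces: the boundary of a mask is the
  mask minus its 6-connected erosion (volume edges count as boundary), and
  each directed distance is the exact Euclidean distance (spacing-weighted,
  via a k-d tree) from a boundary-voxel centre to the nearest boundary-voxel
  centre of the other mask. Mesh extraction would be smoother but is not
  reproducible against a brute-force oracle; voxel surfaces are.
* **HD95** = max of the two directed 95th percentiles (percentile by linear
  interpolation between order statistics — stated explicitly because HD95
  differs across percentile conventions); a pooled-percentile variant is
  available as a config option.
* **ASSD** = pooled mean of both directed distance lists.

Empty-mask policy: when exactly one mask is empty, DSC is 0 and RVD is 100%
(empty test) or undefined (empty reference); distance metrics are undefined.
Undefined values propagate as NaN with explicit flags and are excluded from
summaries with their counts reported — an undefined distance silently
recorded as 0 would fake perfect agreement.

## Consensus statistics

All voxel-wise agreement statistics are computed over an explicit
**analysis region**: the bounding box of the union of the masks dilated by a
10 mm margin (configurable), optionally intersected with a body mask. The
choice matters because kappa depends on how much trivially-concordant
background enters the contingency table; counting the whole scan inflates
agreement, so the region is structure-local and recorded in every report.
Absolute kappa values are comparable only at a fixed region rule.

**Overall kappa** is Fleiss' multi-rater kappa with two categories over
region voxels. With M raters and k_i foreground votes at voxel i:

    P_i = [k_i(k_i−1) + (M−k_i)(M−k_i−1)] / [M(M−1)]
    P̄  = mean_i P_i,   p̂ = Σ k_i / (nM),   P̄e = p̂² + (1−p̂)²
    κ  = (P̄ − P̄e) / (1 − P̄e)

The z test of the chance-agreement null (κ = 0) uses the Fleiss–Nee–Landis
large-sample variance, which for two categories reduces to
Var₀ = 2 / (n·M·(M−1)) independent of the margins; the p-value is one-sided
(agreement exceeding chance). With region sizes in the tens of thousands of
voxels, any visible agreement yields p far below 0.001 — the informative
quantity is κ itself, banded conventionally (≤0 none, ≤0.2 slight, ≤0.4
fair, ≤0.6 moderate, ≤0.8 substantial, ≤1 almost-perfect). For small regions
where the normal approximation is doubtful, a seeded permutation test
(random cyclic translations of each mask, default 999 permutations) is
available.

**Generalized conformity index** (CI-gen) is the pair-sum form
Σ_{i<j} |A_i ∩ A_j| / Σ_{i<j} |A_i ∪ A_j|: order-invariant, defined for any
number of observers, equal to the Jaccard index at M = 2. A volume-weighted
variant exists in the literature; the pair-sum form is used here and stated
in every output.

**STAPLE** (binary) estimates a consensus probability map W together with
each rater's sensitivity p_j and specificity q_j by EM:

    E-step:  W_i = a_i / (a_i + b_i),
             a_i = f_T Π_j p_j^{d_ij} (1−p_j)^{1−d_ij}
             b_i = (1−f_T) Π_j q_j^{1−d_ij} (1−q_j)^{d_ij}
    M-step:  p_j = Σ W_i d_ij / Σ W_i,   q_j = Σ (1−W_i)(1−d_ij) / Σ (1−W_i)

Initialization p_j = q_j = 0.99; the foreground prior f_T is spatially
uniform, defaulting to the mean foreground fraction across raters within the
region (clamped away from 0 and 1). The E-step runs in log space; collapsed
denominators are clamped at 1e-10 with a warning. Convergence when
max_j(|Δp_j| + |Δq_j|) < 1e-7 or 200 iterations. The observed-data
log-likelihood Σ log(a_i + b_i) is recorded per iteration and is
non-decreasing under EM — the tests assert this on every fixture. The
consensus mask thresholds W at 0.5, ties to foreground.

## Confidence-based fusion

Given M model masks of one structure and the planning CT:

1. **Trimap.** Intersection → definite foreground, complement of the union
   → definite background, remainder → uncertain. M = 2 is fully supported
   (the uncertain region is then the symmetric difference).
2. **Confidence map.** Each uncertain voxel gets c ∈ [0, 1] by solving the
   discrete Laplace (random-walker) equation with Dirichlet conditions c = 1
   on foreground and c = 0 on background, 6-neighbour affinities
   w_uv = exp(−β (I_u − I_v)²/σ²) + 1e-10. The additive floor keeps the
   system nonsingular when strong edges underflow the exponential. β
   (default 2.0) sets edge sensitivity: at the default, intensity steps at
   the noise scale attenuate diffusion mildly while a 2–3σ tissue edge
   blocks it by roughly three orders of magnitude; β = 0 reduces to pure
   lattice interpolation independent of the CT. σ defaults to a robust SD
   (1.4826·MAD) of the CT inside the union bounding box, with a plain-SD
   then 1e-6 fallback for degenerate patches. The sparse system is solved
   directly; the residual is checked against a 1e-8 tolerance. Uncertain
   components with no path to foreground get c = 0, with no path to
   background c = 1 (the harmonic limits). A cheap geometric fallback
   (`method="distance_ratio"`, c = d_BG/(d_FG+d_BG) from Euclidean distance
   transforms, ignoring the CT) exists for very large uncertain regions.
3. **Threshold.** The fused mask is foreground ∪ {uncertain : c ≥ t}, so
   intersection ⊆ fused ⊆ union always, and results are nested in t. The
   comparison carries a 1e-9 slack so voxels at exactly c = t survive solver
   roundoff. Per-structure thresholds are chosen on training cases by
   exhaustive grid search (t ∈ {0.05, …, 0.95}) maximising mean DSC against
   the reference; ties break toward the candidate nearest 0.5 (then the
   smaller), keeping the operating point away from the degenerate
   union/intersection extremes.

For downstream learned fusion, `assemble_channels` stacks the CT (clipped to
[−200, 300] HU — soft-tissue head-and-neck window, configurable — then
min-max scaled, constant images mapping to 0), the agreement map k_i/M, and
the confidence map as aligned float32 channels. Training a network on these
channels is out of scope.

## Synthetic phantoms

No patient data ship with the package; every statistic is exercised on
phantoms. A phantom is a CT-like volume (default 64×64×48 voxels at
(1, 1, 3) mm — 3 mm slices being typical of planning CTs) with analytic
truth structures: voxel centres inside an implicit sphere / ellipsoid / tube
/ box, each at a recipe HU, plus seeded Gaussian noise (default SD 15 HU, a
realistic planning-CT noise floor). The default menu spans the agreement
spectrum seen clinically: a large high-contrast mandible-like box (+800 HU),
a mid-size parotid-like ellipsoid (+45 HU), and small low-contrast lens-
(r = 3 mm, +35 HU) and pituitary-like (r = 4 mm, +30 HU) spheres.

Simulated "model outputs" perturb the truth in three seeded stages: a rigid
Gaussian shift per axis (mm, rounded to voxels), a signed morphological
dilation/erosion, and random flips of voxels within one voxel of the
boundary. Severity presets bundle the parameters (shift SD mm / morph radius
/ flip rate): none = identity, low (0.5, ±1, 0.02), medium (1.0, ±1, 0.05),
high (2.0, ±2, 0.10), spanning roughly the DSC range 0.5–0.95 reported for
commercial head-and-neck auto-contouring. The morph radius (and the flip
band) is interpreted as a **physical** distance, radius × min(spacing):
on an anisotropic grid a 1-voxel morph acts in-plane rather than adding or
removing whole 3 mm slices, which would otherwise dwarf every other stage
for thin structures and push small-organ DSC far below the intended
severity span. On isotropic grids this is the ordinary 6-connected ball.
Randomness derives from one root seed through fixed substreams
(`SeedSequence([root, case, stage, observer])`), so outputs are
bit-reproducible and adding an observer never perturbs existing ones.

What the phantoms emulate: controllable inter-model variability, structure
size/contrast effects on agreement (small low-contrast bodies score lower
kappa than large sharp ones), and the geometry that drives the fusion
pipeline. What they do not emulate: realistic CT texture and artefacts,
deformable (elastic) contour disagreement, systematic vendor bias shared
across patients, or anatomically correlated errors. Passing phantom tests
therefore demonstrates correctness of the statistics and the fusion
machinery, not clinical performance on patient data.

### A measured limitation of the fusion under harsh conditions

Across seeded medium-severity phantom cohorts, fusion with trained
per-structure thresholds raises the pooled mean DSC against truth by about
0.12 over the individual simulated models. It does not, however, reduce the
pooled DSC spread: for the 31-voxel lens-like structure, the four simulated
observers occasionally share no voxel at all; the trimap then has no
definite foreground, the confidence map is identically zero, and the fused
contour is empty (DSC 0). These rare catastrophic failures make the fused
DSC distribution bimodal and its SD slightly larger than the noisiest
individual observer's, even as its mean improves. This is a property of
intersection-seeded fusion itself: when the sources are mutually disjoint
there is no high-confidence core to grow from. In clinical use the
corresponding signal (an empty intersection across vendors) is itself a
review flag.

## Reporting conventions

Long-format metric tables aggregate to mean ± sample (n−1) SD per
(structure, source), with undefined entries excluded and counted. Means
beyond the conventional attention thresholds — DSC < 0.7, RVD > 30%,
HD95 > 5 mm, ASSD > 3 mm — are flagged, mirroring how published evaluation
tables bold problem structures; the thresholds are config-overridable. CSV
output is UTF-8, comma-separated, "." decimal, header mandatory; every CLI
run writes a YAML snapshot of its effective configuration sufficient to
reproduce it, and identically seeded runs are bit-identical on one platform.

Problem sizes used by the shipped verification runs (test suite and
`scripts/acceptance.py`): default-size phantoms, 4 observers, cohorts of
6–8 training and 12–20 evaluation cases — large enough for the stochastic
tendencies to be stable at fixed seeds while the whole suite runs in well
under a minute.
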