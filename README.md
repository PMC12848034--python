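# contourkit

Consistency evaluation and training-free fusion of multi-model radiotherapy
contours.

## The problem

Commercial deep-learning auto-contouring systems now draw the gross tumour
volume (GTV) and organs at risk (OARs) on planning CTs in minutes, but
different systems disagree — especially on small or low-contrast structures
(lenses, pituitary, temporomandibular joints) — and a clinic running several
tools needs to quantify that disagreement before trusting any of them.
`contourkit` is for medical-physics and radiation-oncology researchers who
have, per patient, one CT and M ≥ 2 binary masks per structure (from
different models or observers, as NIfTI labels or DICOM RT-STRUCT contours)
and want to:

1. **score** each contour against a reference — Dice similarity coefficient
   (DSC = 2|A∩B|/(|A|+|B|)), relative volume difference
   (RVD = |V_t−V_r|/V_r·100%), 95th-percentile Hausdorff distance (HD95, mm)
   and average symmetric surface distance (ASSD, mm);
2. **measure inter-model agreement** — per-case volume summaries
   (min/max/mean/SD, intersection, union), the voxel-wise overall Fleiss
   kappa κ = (P̄−P̄e)/(1−P̄e) with its z-test of the chance-agreement null
   κ = 0, the generalized conformity index
   CI-gen = Σ_{i<j}|A_i∩A_j| / Σ_{i<j}|A_i∪A_j|, and binary STAPLE
   (EM-estimated consensus probability map plus per-rater sensitivity p_j
   and specificity q_j);
3. **fuse** the M masks into one contour with no additional training:
   the mask intersection becomes definite foreground and the union's
   complement definite background (a trimap); each uncertain voxel receives
   a confidence c ∈ [0,1] by solving the random-walker Laplace equation on
   the CT with affinities exp(−β(ΔI)²/σ²); a per-structure threshold chosen
   on training cases to maximise DSC produces the final mask, which always
   satisfies intersection ⊆ fused ⊆ union.

Because patient data cannot ship with the code, the package includes a
phantom generator: CT-like volumes with analytic truth structures (large
high-contrast mandible-like bodies down to 3 mm low-contrast lens-like
spheres) and M seeded, severity-controlled simulated model outputs, so the
whole pipeline is testable end to end. See `docs/methods.md` for formulas,
defaults and limitations.

## Worked example

```python
import numpy as np
import contourkit as ck

# one synthetic case: CT-like volume + 4 simulated model contours per structure
ct, truths = ck.make_phantom(ck.default_phantom_spec(seed=7))
truth = truths["parotid_like"]
models = ck.generate_observer_set(
    truth, 4, ck.PerturbationSpec.from_severity("medium", seed=7)
)

# 1. geometric agreement of each model against the reference
for m in models:
    r = ck.evaluate_pair(m, truth)
    print(f"{m.source}: DSC={r.dsc:.3f} RVD={r.rvd:.1f}% "
          f"HD95={r.hd95:.2f}mm ASSD={r.assd:.2f}mm")

# 2. inter-model consensus
kr = ck.overall_kappa(models)
print(f"overall kappa={kr.kappa:.3f} ({ck.classify_agreement(kr.kappa)}), "
      f"p={kr.p_value:.2g}, CI-gen={ck.ci_gen(models):.3f}")
sr = ck.staple(models)
print("STAPLE sensitivities:", np.round(sr.sensitivity, 3))

# 3. training-free confidence fusion
fused = ck.fuse(ct, models, threshold=0.5)
print(f"fused DSC={ck.dice(fused, truth):.3f}")
```

Output:

```
model-1: DSC=0.817 RVD=19.9% HD95=3.00mm ASSD=0.88mm
model-2: DSC=0.788 RVD=0.4% HD95=2.83mm ASSD=1.05mm
model-3: DSC=0.875 RVD=22.2% HD95=2.24mm ASSD=0.60mm
model-4: DSC=0.884 RVD=20.2% HD95=2.00mm ASSD=0.52mm
overall kappa=0.730 (substantial), p=0, CI-gen=0.591
STAPLE sensitivities: [0.76  0.81  0.926 0.762]
fused DSC=0.985
```

Reading it: the four simulated models each overlap the truth at DSC
0.79–0.88 with sub-3 mm HD95 — decent individual contours with substantial
but imperfect mutual agreement (κ = 0.73). Fusing them through the
CT-driven confidence map recovers the truth at DSC 0.985, better than every
individual input, because voxels where the models disagree are kept only
when the image supports them.

## Command line

Each subcommand reads a case manifest CSV
(`case,structure,role,path,format`; roles `reference`, `model-k`, `image`)
and writes CSV/JSON results plus a YAML config snapshot to `--out`:

```sh
contourkit phantom --out data --cases 10 --observers 4 --severity medium --seed 1
contourkit metrics --manifest data/manifest.csv --out results
contourkit consensus --manifest data/manifest.csv --out results --export-staple
contourkit select-threshold --manifest data/manifest.csv --out results
contourkit fuse --manifest data/manifest.csv --out results \
    --thresholds-json results/thresholds.json
contourkit report --manifest data/manifest.csv --out results   # all of the above
```

`metrics_summary.csv` reports mean ± SD per (structure, source) and flags
cells beyond the conventional attention thresholds (DSC < 0.7, RVD > 30%,
HD95 > 5 mm, ASSD > 3 mm). Identically seeded runs reproduce their outputs
bit for bit.

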