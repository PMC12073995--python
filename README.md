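# pvspet

Quantitative PET-MRI analysis of perivascular spaces (PVS) in cerebral
small vessel disease, as a tested Python pipeline.

Enlarged perivascular spaces are an MRI-visible marker of small vessel
disease, and a central open question is whether the tissue immediately
around them is inflamed (activated microglia, measured by TSPO-tracer PET)
or leaks at the blood-brain barrier (measured by dynamic contrast-enhanced
MRI). `pvspet` implements the full analysis chain needed to ask that
question quantitatively:

- **DCE-MRI permeability** (`relaxometry_dce`): variable-flip-angle SPGR T1
  mapping, gadolinium concentration via 1/T1(t) = 1/T1₀ + r1·C(t), a
  sagittal-sinus input function corrected by 1/(1 − haematocrit), and
  Patlak graphical analysis — C_t/C_p regressed on ∫C_p/C_p — whose slope
  is the BBB influx rate K_i (min⁻¹) and intercept the plasma fraction v_p.
- **PET kinetics** (`pet_kinetics`): binding potential BP_ND by a
  basis-function simplified reference tissue model,
  C_t = R1·C_r + (k2 − R1·θ₃)(C_r ⊗ e^{−θ₃t}), with vascular binding
  handled as an extra linear regressor built from the ten hottest
  early-frame voxels, plus pre-fit Gaussian smoothing.
- **PVS morphometry** (`pvs_morphometry`): the count-based 0–4 visual
  rating (0 / 1–10 / 11–20 / 21–40 / >40 PVS in the busiest axial slice),
  regional volumes with brain-volume-normalised log transforms, white-matter
  mask erosion, and concentric "penumbra" shells — one, two and three
  voxel dilations of the PVS mask, restricted to white matter.
- **Statistics** (`association_stats`): repeated-measures ANOVA with
  Bonferroni paired t-tests across penumbra layers, covariate-adjusted
  Spearman and linear associations (age and sex as covariates),
  Benjamini–Hochberg FDR, blood-biomarker plate-median normalisation with
  Shapiro–Wilk-driven transforms, PCA summaries, and joint
  proportional-odds / linear models.
- **Synthetic phantoms** (`phantom`): tissue label volumes, tubular PVS,
  dynamic PET and DCE series generated from the exact forward models with
  closed-form exponential curves, and cohort tables with configurable
  PVS-to-BP_ND effect size — every fitter is validated by forward/inverse
  closure against known ground truth.

## Worked example

Simulate a phantom brain with PVS whose surroundings bind extra tracer,
map BP_ND with vascular correction, and summarise the penumbra:

```python
import numpy as np
from pvspet import phantom as ph
from pvspet import pet_kinetics as pk
from pvspet import pvs_morphometry as pvm

tissue = ph.make_tissue_phantom((48, 48, 48), seed=1)
pvs, _ = ph.make_pvs_tubes(tissue, n_wm=12, n_bg=4, seed=2)
blood = ph.make_blood_region(tissue)
kin = ph.PETKinetics(pvs_bp_increment=0.15)   # extra binding near PVS
dyn, truth = ph.simulate_pet(tissue, pvs, kin, vascular_fraction=0.05,
                             blood_mask=blood, seed=3)

brain = tissue.mask(ph.GM, ph.WM, ph.BG)
vascular = pk.extract_vascular_curve(dyn, brain | blood.astype_bool())
smoothed = pk.smooth_gaussian(dyn, fwhm_mm=4.0)
maps = pk.bpnd_map(smoothed, truth.reference_tac, vascular=vascular,
                   brain_mask=brain)

wm = tissue.mask(ph.WM)
score, _ = pvm.visual_rating(pvs, wm)
shells = pvm.build_penumbra(pvs, wm)
print(pvm.shell_means(shells, maps["bp_nd"]).to_string(index=False))
mean_bp, cbrt = pk.mean_bpnd(maps["bp_nd"], wm)
print(f"WM PVS visual score: {score}")
print(f"WM mean BP_ND: {mean_bp:.4f} (cube-root {cbrt:.4f})")
```

Output:

```
 layer  n_voxels     mean       sd
   PVS       284 0.374902 0.011813
layer1      1718 0.362243 0.020635
layer2      3322 0.342702 0.027570
layer3      4037 0.327068 0.027669
WM PVS visual score: 1
WM mean BP_ND: 0.3280 (cube-root 0.6897)
```

The per-layer means fall monotonically with distance from the PVS —
recovering the simulated binding gradient (white-matter baseline BP_ND 0.30
plus an increment decaying from the PVS surface) — and the busiest slice
holds 1–10 PVS, hence visual score 1. The cube-root value is the normality
transform used downstream by the association models.

The same stages are scriptable from the shell via the `pvspet` console
command (`phantom`, `t1map`, `patlak`, `srtm`, `pvs`, `penumbra`, `stats`,
and `all`, which runs the end-to-end pipeline from a YAML config and writes
K_i/BP_ND maps, shell tables and association tables with a logged seed).

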