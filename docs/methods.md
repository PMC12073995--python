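# Methods

`pvspet` implements a quantitative PET-MRI analysis of perivascular spaces
(PVS) in cerebral small vessel disease: blood-brain-barrier (BBB)
permeability mapping from dynamic contrast-enhanced (DCE) MRI, TSPO-tracer
binding-potential mapping from dynamic PET, PVS morphometry with concentric
"penumbra" shells, and the cohort statistics linking them. Because no
patient data ship with the package, every stage is exercised against a
synthetic phantom whose ground truth is known exactly; this note records the
models, the defaults and why, and what the synthetic tests do and do not
demonstrate.

## Units and conventions

Times are minutes, activities kBq/ml, gadolinium concentrations mmol/L, T1
in milliseconds, K_i in min^-1, spacing in mm. Voxel indices are 0-based;
world coordinates come from the NIfTI affine. Morphology (dilation, erosion
radius conversion aside) acts in voxel space because the penumbra
construction is defined in voxel steps. Non-physical fits propagate as NaN
plus a validity mask, never as zeros.

## T1 mapping and Patlak permeability

The variable-flip-angle (VFA) fit linearises the spoiled gradient-echo
signal S(α) = M0 sinα (1−E1)/(1−E1 cosα), E1 = exp(−TR/T1): regressing
S/sinα on S/tanα gives slope E1 and intercept M0(1−E1). Voxels with slope
outside (0,1) — or with relative lack of fit above 2×10⁻³, which catches
signals no SPGR parameter pair can produce (e.g. identical at all angles) —
are flagged invalid. On noiseless data at the protocol's six angles
(2–27°, TR 6.3 ms) recovery is exact to well below 0.1%.

Dynamic phases are acquired at a single flip angle (default 12°); T1(t) is
inverted from the SPGR equation using the baseline M0 rather than refitting
all angles per phase. Concentration follows C(t) = (1/T1(t) − 1/T1₀)/r1 with
the gadoterate relaxivity r1 defaulting to 3.5 L mmol⁻¹ s⁻¹ at 3 T
(configurable; the acquisition protocol does not pin it down). The plasma
input function is the mean whole-blood concentration over a sagittal-sinus
mask divided by (1 − haematocrit) (default Hct 0.45 when no subject value is
available). Patlak graphical analysis regresses C_t/C_p on ∫C_p/C_p
(trapezoidal integral) over phases with C_p > 0 and t ≥ t_start (default
0.5 min, the first post-injection phase; the analysis window is
configurable): the slope is K_i, the intercept v_p. The voxelwise map shares
one design matrix across voxels, so the fit is a single batched solve.

Numerical accuracy of the inverse chain depends on the phase sampling
because the plasma integral is trapezoidal against a sharply rising bolus:
at the protocol's 15-s resolution the noiseless closed-loop error on
(K_i = 3×10⁻⁴ min⁻¹, v_p = 0.01) is ≈0.3%; halving the resolution roughly
quadruples it.

## SRTM binding-potential mapping

The simplified reference tissue model is fitted with a basis-function
scheme: for each θ₃ on a log-spaced grid (64 points in [0.006, 0.6] min⁻¹ by
default) the model C_t = θ₁C_r + θ₂(C_r ⊗ e^{−θ₃t}) is linear; the grid
point minimising the duration-weighted residual wins, and parameters map to
R1 = θ₁, k2 = θ₂ + R1θ₃, BP_ND = k2/θ₃ − 1. The convolution integrates the
exponential exactly against a piecewise-linear reference curve (frame
durations vary by an order of magnitude across the 55-frame schedule, so
sample-grid quadrature would corrupt the early frames). Weights are frame
durations, a proxy for count statistics. BP_ND may be negative — the target
cohort's white matter binds less tracer than the control-population
reference — and is not clipped.

Vascular binding is corrected by adding the whole-blood curve as one more
linear regressor per basis subproblem, coefficient unconstrained, estimated
per voxel. The blood curve itself is measured from the data: voxels are
ranked by summed activity over the first five frames and the ten hottest are
averaged over the full time course (ties broken by voxel index, so the
output is deterministic). In the pipeline this extraction runs on the
*unsmoothed* series: the phantom's blood pool is a small blob, and the 4 mm
FWHM Gaussian applied before mapping would dilute its early peak with tissue
kinetics, visibly biasing BP_ND. Smoothing (σ = FWHM/2√(2 ln 2), converted
per-axis by spacing) is then applied before the voxelwise fit, as in the
source protocol.

On noiseless forward curves the grid fit recovers (R1, k2, BP_ND) to well
under 5% (the θ₃ grid ratio is ≈1.076, and the linear coefficients absorb
most of the residual grid error), matches a direct nonlinear least-squares
oracle within a grid step, and with the vascular regressor recovers a 5%
blood admixture essentially exactly, while omitting the regressor inflates
BP_ND by ≈19% — the rationale for the correction.

## PVS morphometry and penumbra

The count-based visual rating is automated: per axial slice, 2D connected
components (8-connectivity) of the PVS mask within the region are counted;
the maximum slice count N maps to 0 (N=0), 1 (1–10), 2 (11–20), 3 (21–40),
4 (>40). A human rater estimates counts; component counting is the
operationalisation that reproduces the published category boundaries and is
testable.

Volumes are voxel count × voxel volume (cm³), regionally via mask
intersection; normalised volumes are ln(volume/brain volume), with zero
volumes excluded (flagged None) rather than offset by a pseudo-count. The
white-matter mask may be eroded by a world-radius spherical element
(3 mm in the source protocol) to avoid ventricular/grey-matter
contamination.

Penumbra shells: D_k is the k-fold binary dilation of the PVS mask by the
full 3×3×3 (26-connected) structuring element — the reading of "dilating in
all directions"; a 6-connected cross is available via the `connectivity`
argument. Shell k = (D_k \ D_{k−1}) ∩ WM, with the PVS layer itself
restricted to WM; shells are pairwise disjoint by construction, so layer
means never double-count voxels. A single PVS voxel in all-WM space yields
shells of 26/98/218 voxels. Per-layer summaries use valid (finite) voxels
only.

## Cohort statistics

- Shell gradient: one-way repeated-measures ANOVA across the four layers
  (subjects as blocks; F = MS_layer/MS_error with (k−1), (n−1)(k−1) df),
  then all six paired t-tests with Bonferroni multiplier 6. Subjects missing
  a layer are dropped and logged. Identical-layer degenerate input returns
  F=0, p=1. An independent-groups ANOVA is not provided; the paired t-tests
  in the source protocol imply the within-subject reading.
- Covariate-adjusted Spearman: all variables (including covariates) are
  rank-transformed, x and y residualised on the ranked covariates by OLS,
  and the residual Pearson correlation tested with df = n − 2 − #covariates.
  Ranking the covariates matters: residualising ranks on raw covariates
  leaves monotone confounding behind (a property test demonstrates this).
- Linear associations: OLS with age and sex (0/1, male = 1) as covariates;
  standardized β reported alongside raw. Rank-deficient designs are
  rejected by name.
- FDR: Benjamini–Hochberg step-up via statsmodels, validated exactly against
  a brute-force implementation. The family is the rows of each results
  table (five PVS markers per modality), mirroring a per-table correction;
  callers can pool families explicitly.
- Biomarkers: each marker is divided by its per-plate median (batch
  correction), then Shapiro–Wilk at α = 0.05 decides the transform — none,
  log (all-positive markers), else signed cube root — and the choice is
  logged per marker. Kinetic regional means use the signed cube root,
  sign(x)|x|^{1/3}, so negative means stay defined.
- PCA: center + unit-variance scale, scores via SVD (valid when markers
  outnumber subjects, flagged), component signs fixed so the
  largest-magnitude loading is positive — the output is deterministic.
- Joint models: proportional-odds cumulative-logit (statsmodels
  OrderedModel, BFGS, gtol 10⁻⁸) for the ordinal scores and OLS for the
  volumes, with mean BP_ND, mean K_i and PC1–3 as simultaneous predictors
  plus age and sex. The binary special case agrees with logistic regression
  to ≈10⁻⁹. Complete separation is raised as a diagnostic error (detected
  via the convergence flag, non-finite standard errors, or runaway
  coefficients), not silent divergence.

## The synthetic phantom

The phantom defines the study conditions and is first-class, tested code.

- Geometry: concentric ellipsoids — GM shell, WM core, two basal-ganglia
  blobs, central ventricles — at ≥32³ voxels; PVS are digital cylinders
  (default radius 1, length 6 voxels) placed fully inside WM/BG, mutually
  non-adjacent so each is one connected component.
- Curves are sums of decaying exponentials, so the SRTM convolution and the
  Patlak plasma integral have closed forms: the forward data are exact and
  independent of the fitters' discretizations, which is what makes the
  closure tests meaningful. The reference curve is a single uptake-washout
  pair (the source protocol's control-population curves are not
  reproducible, so the reference is supplied explicitly everywhere); the
  blood curve peaks sharply in the first minute; the plasma input is
  bi-exponential with a smooth bolus rise.
- PET: per-tissue (R1, k2, BP_ND), optional BP_ND increment decaying
  exponentially with voxel distance from the PVS mask (emulating elevated
  binding near PVS), optional blood-pool voxels and a global vascular
  fraction, Gaussian noise scaled by 1/√(frame duration). 55 frames tile
  75 min with geometrically increasing durations (frame count from the
  source protocol; the clinical schedule itself is unpublished and the
  "75 min" statement is ambiguous between delay and duration — a 0–75 min
  schedule was chosen and is configurable).
- DCE: Patlak forward concentrations, T1 via relaxivity, SPGR signals for
  the six-angle baseline and the single-angle dynamic series at 15-s
  phases over 24 min; the sinus region carries whole-blood concentration
  C_p(1 − Hct), i.e. exactly the signal the analysis divides by (1 − Hct).
- Cohort: ages ~ N(70.81, 10.61) truncated to [40, 95], 57.4% male,
  log-normal PVS volumes with medians near 1.06 (WM) and 0.33 (BG) cm³;
  ordinal scores discretize a noisy copy of the latent WM burden; mean
  BP_ND = intercept + slope·z + noise with z the standardized log WM PVS
  volume (slope = 0 gives a full null); mean K_i carries no association —
  the null the analysis should report. The 93-marker panel arises from 3
  latent factors plus noise (so a PCA structure exists), a fraction of
  markers exponentiated to emulate right-skewed assays, with multiplicative
  per-plate batch effects. `CohortEffect.for_correlation(ρ)` converts a
  target latent correlation into the slope; ρ = 0.5 approximates the
  study's headline regime after the ordinal discretization attenuates it
  slightly.
- Layer-mean cohorts (`simulate_layer_cohort`) model per-subject penumbra
  means directly: subject intercept ~ N(0, σ_b), shell elevation
  effect·σ_b·(1, 0.5, 0.25, 0), measurement noise σ_w = 0.1 σ_b. A regional
  mean over thousands of voxels has small sampling noise relative to
  between-subject spread, hence the 1:10 ratio; "effect 0.3" therefore
  means 0.3 between-subject SDs at the innermost layer.

What the phantom does **not** emulate: realistic anatomy, partial-volume
effects, scanner point-spread, motion, registration error, B1
inhomogeneity, or human rater variability. Passing tests therefore
demonstrate correctness of the estimators under the stated forward models
and power/size of the statistics under Gaussian conditions — not robustness
to the acquisition artifacts of real data.

## Problem sizes

Default analyses run on 48³ (pipeline: 40³) phantoms, 55 PET frames, 96 DCE
phases, cohorts of 10 (pipeline default) to 500 (statistical checks)
subjects, 100-cohort power runs and 2000-replicate null calibrations —
sizes at which every closure and calibration in the test suite is
informative while a full run stays in the tens of seconds. At n = 10 the
joint cumulative-link model may legitimately fail to converge
(quasi-separation); the pipeline records this in the output table's
`status` column rather than dropping the file.

## Reproducibility

All randomness flows from a single named seed per simulation; the pipeline
derives stage seeds by fixed offsets from the configured seed and logs the
seed and package versions to `run_log.json`. A fixed config reproduces
byte-identical summary tables.
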