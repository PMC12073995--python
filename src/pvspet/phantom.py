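"""Synthetic brain phantoms with known ground truth.

This module generates everything the analysis stages consume — tissue label
volumes, tubular perivascular-space (PVS) masks, dynamic PET series driven by
a simplified-reference-tissue-model (SRTM) forward solution with a vascular
component, multi-flip-angle SPGR baselines plus a dynamic DCE series driven
by a Patlak forward model, and cohort tables with a configurable PVS-to-BP_ND
effect size and a correlated 93-marker blood panel.

All analytic curves (reference, blood, plasma input) are represented as sums
of decaying exponentials, so the SRTM convolution and the Patlak plasma
integral have closed forms: the forward data are exact, independent of the
fitting modules' discretizations, which makes forward/inverse closure tests
meaningful.

Ground truth is returned alongside every simulated dataset and is never
consumed by the analysis stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import DynamicImage, ImageVolume, SubjectRecord, TimeActivityCurve
from .relaxometry_dce import VFASeries, spgr_signal

__all__ = [
    "TissuePhantom",
    "GroundTruth",
    "PETKinetics",
    "AIFParams",
    "CohortEffect",
    "BiomarkerSpec",
    "make_tissue_phantom",
    "make_pvs_tubes",
    "make_blood_region",
    "default_frame_schedule",
    "reference_curve_terms",
    "blood_curve_terms",
    "expsum_eval",
    "simulate_pet",
    "simulate_dce",
    "simulate_cohort",
    "simulate_layer_cohort",
    "cohort_frame",
]

# Tissue label codes
BACKGROUND, GM, WM, BG, VENTRICLE = 0, 1, 2, 3, 4

LABEL_NAMES = {0: "background", 1: "GM", 2: "WM", 3: "BG", 4: "ventricle"}


# ---------------------------------------------------------------------------
# Exponential-sum curves
# ---------------------------------------------------------------------------

def expsum_eval(terms, t):
    """Evaluate sum_i a_i * exp(-r_i * t) at times t (t >= 0)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for a, r in terms:
        out += a * np.exp(-r * t)
    return out


def expsum_integral(terms, t):
    """Closed-form running integral of an exponential sum from 0 to t."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for a, r in terms:
        if abs(r) < 1e-12:
            out += a * t
        else:
            out += a * (1.0 - np.exp(-r * t)) / r
    return out


def expsum_conv_exp(terms, theta, t):
    """Closed-form convolution of an exponential sum with exp(-theta * t).

    ``theta`` may be a scalar or an array (broadcast against a trailing time
    axis), which lets the SRTM forward model vectorise over voxels with
    per-voxel apparent efflux rates.
    """
    t = np.asarray(t, dtype=float)
    theta = np.asarray(theta, dtype=float)
    th = theta[..., None] if theta.ndim else theta
    out = np.zeros(np.broadcast_shapes(np.shape(th), t.shape))
    e_th = np.exp(-th * t)
    for a, r in terms:
        denom = th - r
        safe = np.where(np.abs(denom) < 1e-10, 1.0, denom)
        generic = a * (np.exp(-r * t) - e_th) / safe
        limit = a * t * np.exp(-r * t)  # theta -> r
        out += np.where(np.abs(denom) < 1e-10, limit, generic)
    return out


def reference_curve_terms(amplitude=30.0, uptake_rate=1.0, washout_rate=0.05):
    """Single uptake-washout reference tissue curve,
    C_r(t) = A (e^{-washout t} - e^{-uptake t}), peaking at a few minutes."""
    return [(amplitude, washout_rate), (-amplitude, uptake_rate)]


def blood_curve_terms(amplitude=80.0, fast_rate=4.0, clearance_rate=0.25,
                      tail_amplitude=6.0, tail_rate=0.02):
    """Whole-blood activity curve: a sharp early bolus peak plus a slow tail,
    so blood voxels dominate the first frames of a dynamic PET series."""
    return [
        (amplitude, clearance_rate),
        (-amplitude, fast_rate),
        (tail_amplitude, tail_rate),
        (-tail_amplitude, fast_rate),
    ]


def default_frame_schedule(n_frames=55, total_min=75.0, first_duration=0.25):
    """Frame durations increasing geometrically over the scan.

    Returns (start_min, duration_min) arrays. The growth factor is solved so
    that ``n_frames`` frames of geometrically increasing duration, starting at
    ``first_duration``, exactly tile ``total_min`` minutes.
    """
    from scipy.optimize import brentq

    if n_frames * first_duration >= total_min:
        raise ValueError("first_duration too long for the requested total")

    def excess(g):
        return first_duration * (g ** n_frames - 1.0) / (g - 1.0) - total_min

    g = brentq(excess, 1.0 + 1e-9, 2.0)
    durations = first_duration * g ** np.arange(n_frames)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return starts, durations


# ---------------------------------------------------------------------------
# Tissue phantom and PVS tubes
# ---------------------------------------------------------------------------

@dataclass
class TissuePhantom:
    """Integer label volume: 0 background, 1 GM, 2 WM, 3 basal ganglia,
    4 ventricle."""

    labels: ImageVolume

    def __post_init__(self):
        codes = np.unique(self.labels.data)
        bad = set(codes.tolist()) - {0, 1, 2, 3, 4}
        if bad:
            raise ValueError(f"unexpected label codes: {sorted(bad)}")

    def mask(self, *labels) -> np.ndarray:
        return np.isin(self.labels.data, labels)

    @property
    def spacing(self) -> np.ndarray:
        return self.labels.spacing


def make_tissue_phantom(shape=(48, 48, 48), spacing=(1.0, 1.0, 1.0), seed=0
                        ) -> TissuePhantom:
    """Concentric ellipsoidal brain: GM shell around a WM core, with embedded
    basal-ganglia blobs and central ventricles.

    Deterministic for a fixed seed (the seed jitters blob placement only).
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 32:
        raise ValueError(
            f"shape {shape} too small: every axis must be >= 32 voxels to "
            "contain all tissue classes"
        )
    rng = np.random.default_rng(seed)
    grid = np.indices(shape).astype(float)
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    semi = 0.45 * np.asarray(shape, dtype=float)
    r = np.sqrt(sum(((grid[i] - center[i]) / semi[i]) ** 2 for i in range(3)))

    labels = np.zeros(shape, dtype=np.int16)
    labels[r <= 1.0] = GM
    labels[r <= 0.78] = WM

    # central ventricles: small ellipsoid, slightly jittered
    vcen = center + rng.uniform(-0.02, 0.02, size=3) * np.asarray(shape)
    vsemi = np.array([0.14, 0.10, 0.16]) * np.asarray(shape, dtype=float)
    rv = np.sqrt(sum(((grid[i] - vcen[i]) / vsemi[i]) ** 2 for i in range(3)))
    labels[(rv <= 1.0) & (labels == WM)] = VENTRICLE

    # two basal-ganglia blobs flanking the ventricles
    for sign in (-1.0, 1.0):
        bcen = center + np.array([sign * 0.24 * shape[0], 0.0, 0.0])
        bcen = bcen + rng.uniform(-0.01, 0.01, size=3) * np.asarray(shape)
        bsemi = np.array([0.09, 0.12, 0.12]) * np.asarray(shape, dtype=float)
        rb = np.sqrt(sum(((grid[i] - bcen[i]) / bsemi[i]) ** 2
                         for i in range(3)))
        labels[(rb <= 1.0) & (labels == WM)] = BG

    vol = ImageVolume.from_spacing(labels, spacing)
    phantom = TissuePhantom(vol)
    for code in (GM, WM, BG, VENTRICLE):
        if not np.any(labels == code):
            raise ValueError(
                f"phantom shape {shape} produced an empty "
                f"{LABEL_NAMES[code]} class"
            )
    return phantom


def make_blood_region(phantom: TissuePhantom) -> ImageVolume:
    """Small posterior venous blob (a sagittal-sinus stand-in).

    Serves as the blood pool for PET (hottest voxels early, feeding the
    vascular-curve extraction) and as the sinus region carrying whole-blood
    gadolinium in the DCE simulation.
    """
    labels = phantom.labels.data
    shape = labels.shape
    blob = np.zeros(shape, dtype=bool)
    cx, cy, cz = shape[0] // 2, int(0.88 * shape[1]), shape[2] // 2
    blob[cx - 1:cx + 2, cy - 2:cy + 1, cz - 3:cz + 4] = True
    blob &= labels == GM
    if not blob.any():  # geometry too small: take some outer GM voxels
        gm_idx = np.argwhere(labels == GM)
        blob[tuple(gm_idx[:20].T)] = True
    return ImageVolume(blob, phantom.labels.affine)


def _tube_voxels(center, direction, radius, half_length, shape):
    """Voxel indices of a digital cylinder around a segment."""
    lo = np.maximum(np.floor(center - half_length - radius - 1), 0).astype(int)
    hi = np.minimum(np.ceil(center + half_length + radius + 2),
                    shape).astype(int)
    sub = np.indices(tuple(hi - lo)).reshape(3, -1).T + lo
    rel = sub - center
    t = rel @ direction
    t = np.clip(t, -half_length, half_length)
    nearest = center + t[:, None] * direction
    dist = np.linalg.norm(sub - nearest, axis=1)
    return sub[dist <= radius]


def make_pvs_tubes(phantom: TissuePhantom, n_wm=12, n_bg=4, radius_vox=1.0,
                   length_vox=6.0, seed=0, max_attempts=500):
    """Place random-orientation digital cylinders fully inside WM and BG.

    Tubes are kept mutually non-adjacent (26-connectivity) so that each tube
    is a separate connected component. Returns ``(mask, tube_voxel_lists)``.

    Raises RuntimeError naming the achieved count when a region cannot host
    the requested number of tubes within ``max_attempts`` tries per tube.
    """
    if n_wm < 0 or n_bg < 0:
        raise ValueError("tube counts must be non-negative")
    rng = np.random.default_rng(seed)
    shape = phantom.labels.shape
    mask = np.zeros(shape, dtype=bool)
    blocked = np.zeros(shape, dtype=bool)  # mask dilated by 1: adjacency guard
    tubes = []

    for region_label, n_tubes, region_name in (
        (WM, n_wm, "WM"), (BG, n_bg, "BG"),
    ):
        region = phantom.mask(region_label)
        candidates = np.argwhere(region)
        placed = 0
        attempts = 0
        while placed < n_tubes:
            if attempts >= max_attempts:
                raise RuntimeError(
                    f"could not place tube {placed + 1}/{n_tubes} in "
                    f"{region_name} after {max_attempts} attempts "
                    f"(achieved {placed})"
                )
            attempts += 1
            center = candidates[rng.integers(len(candidates))].astype(float)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            vox = _tube_voxels(center, direction, radius_vox,
                               length_vox / 2.0, np.asarray(shape))
            if len(vox) == 0:
                continue
            idx = tuple(vox.T)
            if not region[idx].all():
                continue
            if blocked[idx].any():
                continue
            mask[idx] = True
            tube_block = np.zeros(shape, dtype=bool)
            tube_block[idx] = True
            blocked |= ndimage.binary_dilation(
                tube_block, structure=np.ones((3, 3, 3), dtype=bool))
            tubes.append(vox)
            placed += 1
            attempts = 0

    return ImageVolume(mask, phantom.labels.affine), tubes


# ---------------------------------------------------------------------------
# Dynamic PET simulation (SRTM forward)
# ---------------------------------------------------------------------------

@dataclass
class PETKinetics:
    """Per-tissue SRTM parameters plus an optional PVS-proximity BP_ND
    increment.

    ``per_tissue`` maps label code -> (R1, k2 [min^-1], BP_ND). The increment
    emulates elevated tracer binding near perivascular spaces: true BP_ND is
    raised by ``pvs_bp_increment * exp(-d / pvs_decay_vox)`` where d is the
    Euclidean voxel distance from the PVS mask.
    """

    per_tissue: dict = field(default_factory=lambda: {
        GM: (1.1, 0.12, 0.35),
        WM: (0.9, 0.10, 0.30),
        BG: (1.0, 0.11, 0.40),
        VENTRICLE: (0.3, 0.05, 0.0),
    })
    pvs_bp_increment: float = 0.0
    pvs_decay_vox: float = 2.0

    def __post_init__(self):
        for label, (r1, k2, bp) in self.per_tissue.items():
            if bp <= -1.0:
                raise ValueError(
                    f"BP_ND must exceed -1 (label {label} has {bp})")
            if k2 <= 0:
                raise ValueError(f"k2 must be positive (label {label})")


@dataclass
class GroundTruth:
    """True per-voxel parameter maps and curves for a simulated dataset.

    Stored alongside every generated dataset as a recovery oracle; never fed
    to the analysis stages.
    """

    bp_map: ImageVolume | None = None
    r1_map: ImageVolume | None = None
    k2_map: ImageVolume | None = None
    ki_map: ImageVolume | None = None
    vp_map: ImageVolume | None = None
    pvs_mask: ImageVolume | None = None
    reference_tac: TimeActivityCurve | None = None
    blood_tac: TimeActivityCurve | None = None
    plasma_tac: TimeActivityCurve | None = None
    params: dict = field(default_factory=dict)


def simulate_pet(phantom: TissuePhantom, pvs_mask, kinetics: PETKinetics,
                 vascular_fraction=0.0, noise_sd=0.0, frame_schedule=None,
                 seed=0, blood_mask=None, reference_terms=None,
                 blood_terms=None):
    """Simulate a dynamic PET series with the SRTM forward model.

    Each brain voxel's time-activity curve is the exact SRTM solution

        C_t(t) = R1 C_r(t) + (k2 - R1 k2a) [C_r * exp(-k2a t)](t),
        k2a = k2 / (1 + BP_ND),

    driven by the analytic reference curve, plus ``vascular_fraction`` times
    the whole-blood curve, plus i.i.d. Gaussian noise with per-frame SD
    ``noise_sd / sqrt(frame duration)``. Voxels in ``blood_mask`` carry the
    pure blood curve. Returns ``(DynamicImage, GroundTruth)``.
    """
    if frame_schedule is None:
        starts, durations = default_frame_schedule()
    else:
        starts, durations = (np.asarray(a, dtype=float)
                             for a in frame_schedule)
    if np.any(durations <= 0):
        raise ValueError("frame durations must be positive")
    mid_times = starts + durations / 2.0

    if reference_terms is None:
        reference_terms = reference_curve_terms()
    if blood_terms is None:
        blood_terms = blood_curve_terms()

    shape = phantom.labels.shape
    labels = phantom.labels.data
    pvs = pvs_mask.astype_bool() if isinstance(pvs_mask, ImageVolume) \
        else np.asarray(pvs_mask, dtype=bool)

    r1_map = np.zeros(shape)
    k2_map = np.full(shape, np.nan)
    bp_map = np.full(shape, np.nan)
    for label, (r1, k2, bp) in kinetics.per_tissue.items():
        sel = labels == label
        r1_map[sel] = r1
        k2_map[sel] = k2
        bp_map[sel] = bp

    brain = np.isin(labels, list(kinetics.per_tissue))
    if kinetics.pvs_bp_increment != 0.0 and pvs.any():
        dist = ndimage.distance_transform_edt(~pvs)
        bp_map[brain] += (kinetics.pvs_bp_increment
                          * np.exp(-dist[brain] / kinetics.pvs_decay_vox))
    if np.any(bp_map[brain] <= -1.0):
        raise ValueError("true BP_ND fell below -1 after the PVS increment")

    c_ref = expsum_eval(reference_terms, mid_times)
    c_blood = expsum_eval(blood_terms, mid_times)

    data = np.zeros(shape + (len(mid_times),))
    r1v = r1_map[brain]
    k2v = k2_map[brain]
    bpv = bp_map[brain]
    k2a = k2v / (1.0 + bpv)
    conv = expsum_conv_exp(reference_terms, k2a, mid_times)
    tacs = r1v[:, None] * c_ref[None, :] + \
        ((k2v - r1v * k2a))[:, None] * conv
    if vascular_fraction:
        tacs = tacs + vascular_fraction * c_blood[None, :]
    data[brain] = tacs

    if blood_mask is not None:
        bl = blood_mask.astype_bool() if isinstance(blood_mask, ImageVolume) \
            else np.asarray(blood_mask, dtype=bool)
        data[bl] = c_blood

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(
            0.0, 1.0, size=data.shape) * (noise_sd / np.sqrt(durations))

    dyn = DynamicImage(data, mid_times, durations, phantom.labels.affine)
    truth = GroundTruth(
        bp_map=ImageVolume(np.where(brain, bp_map, np.nan),
                           phantom.labels.affine),
        r1_map=ImageVolume(np.where(brain, r1_map, np.nan),
                           phantom.labels.affine),
        k2_map=ImageVolume(np.where(brain, k2_map, np.nan),
                           phantom.labels.affine),
        pvs_mask=ImageVolume(pvs, phantom.labels.affine),
        reference_tac=TimeActivityCurve(mid_times, c_ref, kind="reference"),
        blood_tac=TimeActivityCurve(mid_times, c_blood, kind="vascular"),
        params={"vascular_fraction": vascular_fraction,
                "noise_sd": noise_sd, "seed": seed},
    )
    return dyn, truth


# ---------------------------------------------------------------------------
# DCE-MRI simulation (Patlak forward)
# ---------------------------------------------------------------------------

@dataclass
class AIFParams:
    """Bi-exponential plasma input with a smooth bolus rise.

    C_p(t) = (A1 e^{-m1 t} + A2 e^{-m2 t}) (1 - e^{-m0 t}),  in mmol/L.
    Still a pure exponential sum, so the Patlak plasma integral is exact.
    """

    a1: float = 1.2
    m1: float = 0.17   # fast distribution, min^-1
    a2: float = 0.4
    m2: float = 0.011  # slow clearance, min^-1
    rise: float = 8.0  # bolus arrival sharpness, min^-1

    def terms(self):
        return [
            (self.a1, self.m1), (-self.a1, self.m1 + self.rise),
            (self.a2, self.m2), (-self.a2, self.m2 + self.rise),
        ]


DEFAULT_T1_MS = {GM: 1300.0, WM: 800.0, BG: 1100.0, VENTRICLE: 3000.0}
BLOOD_T1_MS = 1650.0

PROTOCOL_FLIP_ANGLES_DEG = (2.0, 5.0, 12.0, 17.0, 22.0, 27.0)


@dataclass
class DCESimulation:
    """Bundle returned by :func:`simulate_dce`."""

    vfa: VFASeries
    dynamic: DynamicImage
    sinus_mask: ImageVolume
    truth: GroundTruth


def simulate_dce(phantom: TissuePhantom, ki_map, vp_map,
                 aif: AIFParams | None = None,
                 vfa_angles_deg=PROTOCOL_FLIP_ANGLES_DEG, tr_ms=6.3,
                 r1_relaxivity=3.5, baseline_t1_ms=None, noise_sd=0.0,
                 phase_times=None, seed=0, dynamic_flip_deg=12.0,
                 haematocrit=0.45, sinus_mask=None) -> DCESimulation:
    """Simulate a variable-flip-angle baseline plus a dynamic DCE series.

    Tissue gadolinium follows the Patlak forward model
    C_t(t) = K_i * int_0^t C_p + v_p * C_p(t); a designated sagittal-sinus
    region carries whole-blood concentration C_p * (1 - haematocrit), i.e.
    the signal from which the analysis recovers plasma via the (1 - Hct)
    correction. Concentration maps to T1 through 1/T1 = 1/T1_0 + r1 * C and
    T1 to SPGR signal at the acquisition flip angle.
    """
    if aif is None:
        aif = AIFParams()
    if phase_times is None:
        phase_times = np.arange(96) * 0.25  # 15-s phases over 24 min
    phase_times = np.asarray(phase_times, dtype=float)

    ki = ki_map.data if isinstance(ki_map, ImageVolume) else np.asarray(ki_map)
    vp = vp_map.data if isinstance(vp_map, ImageVolume) else np.asarray(vp_map)
    if np.any(ki < 0):
        raise ValueError("K_i map must be non-negative")
    if np.any((vp < 0) | (vp >= 1)):
        raise ValueError("v_p map must lie in [0, 1)")
    if not (0.0 < haematocrit < 1.0):
        raise ValueError("haematocrit must lie in (0, 1)")

    labels = phantom.labels.data
    shape = labels.shape
    if baseline_t1_ms is None:
        baseline_t1_ms = DEFAULT_T1_MS
    t1_0 = np.full(shape, np.nan)
    for label, t1 in baseline_t1_ms.items():
        t1_0[labels == label] = float(t1)
    brain = np.isin(labels, list(baseline_t1_ms))
    if np.any(t1_0[brain] <= 0):
        raise ValueError("baseline T1 must be positive")
    m0 = np.where(brain, 1.0, 0.0)

    if sinus_mask is None:
        sinus = make_blood_region(phantom).astype_bool()
    else:
        sinus = sinus_mask.astype_bool() if isinstance(sinus_mask, ImageVolume) \
            else np.asarray(sinus_mask, dtype=bool)

    terms = aif.terms()
    cp = expsum_eval(terms, phase_times)
    cp_int = expsum_integral(terms, phase_times)

    # concentration per voxel per phase
    conc = (ki[..., None] * cp_int[None, None, None, :]
            + vp[..., None] * cp[None, None, None, :])
    conc[~brain] = 0.0
    conc[sinus] = (1.0 - haematocrit) * cp  # whole-blood concentration
    t1_0 = np.where(sinus, BLOOD_T1_MS, t1_0)

    rng = np.random.default_rng(seed)

    # baseline VFA volumes (pre-contrast)
    vfa_vols = []
    for alpha in vfa_angles_deg:
        sig = np.where(brain, spgr_signal(m0, t1_0, tr_ms, alpha), 0.0)
        if noise_sd > 0:
            sig = sig + rng.normal(0.0, noise_sd, size=shape)
        vfa_vols.append(ImageVolume(sig, phantom.labels.affine))
    vfa = VFASeries(vfa_vols, list(vfa_angles_deg), tr_ms)

    # dynamic series at a single acquisition flip angle
    r1_0 = 1000.0 / t1_0  # s^-1
    r1_t = r1_0[..., None] + r1_relaxivity * conc
    t1_t = 1000.0 / r1_t
    dyn_data = np.where(brain[..., None] | sinus[..., None],
                        spgr_signal(m0[..., None], t1_t, tr_ms,
                                    dynamic_flip_deg),
                        0.0)
    if noise_sd > 0:
        dyn_data = dyn_data + rng.normal(0.0, noise_sd, size=dyn_data.shape)

    if len(phase_times) > 1:
        dt = float(np.median(np.diff(phase_times)))
    else:
        dt = 0.25
    dynamic = DynamicImage(dyn_data, phase_times, np.full(
        len(phase_times), dt), phantom.labels.affine)

    truth = GroundTruth(
        ki_map=ImageVolume(np.where(brain, ki, np.nan),
                           phantom.labels.affine),
        vp_map=ImageVolume(np.where(brain, vp, np.nan),
                           phantom.labels.affine),
        plasma_tac=TimeActivityCurve(phase_times, cp, kind="plasma_input"),
        params={"haematocrit": haematocrit, "r1_relaxivity": r1_relaxivity,
                "tr_ms": tr_ms, "dynamic_flip_deg": dynamic_flip_deg,
                "baseline_t1_ms": dict(baseline_t1_ms), "seed": seed},
    )
    return DCESimulation(vfa, dynamic, ImageVolume(
        sinus, phantom.labels.affine), truth)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortEffect:
    """PVS-burden to BP_ND effect in the simulated cohort.

    ``mean_bpnd = intercept + slope * z + Normal(0, noise_sd)`` where z is the
    standardized log WM PVS volume. With ``slope = 0`` all null associations
    hold. ``for_correlation`` converts a target latent Pearson correlation to
    the slope, ``slope = noise_sd * rho / sqrt(1 - rho^2)``.
    """

    slope: float = 0.0
    intercept: float = -0.05
    noise_sd: float = 0.03

    def __post_init__(self):
        if not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise ValueError("effect slope/intercept must be finite")
        if self.noise_sd <= 0:
            raise ValueError("effect noise_sd must be positive")

    @classmethod
    def for_correlation(cls, rho, intercept=-0.05, noise_sd=0.03):
        if not (-1.0 < rho < 1.0):
            raise ValueError("target correlation must lie in (-1, 1)")
        slope = noise_sd * rho / np.sqrt(1.0 - rho ** 2)
        return cls(slope=slope, intercept=intercept, noise_sd=noise_sd)


@dataclass
class BiomarkerSpec:
    """Latent-factor blood panel: ``n_markers`` markers generated from
    ``n_factors`` shared factors plus noise, a fraction exponentiated to
    emulate right-skewed (log-normal) assays, with multiplicative per-plate
    batch effects."""

    n_markers: int = 93
    n_factors: int = 3
    loading_sd: float = 1.0
    noise_sd: float = 0.5
    lognormal_fraction: float = 0.3
    plate_size: int = 30
    plate_effect_sd: float = 0.1

    def __post_init__(self):
        if self.n_markers < 1 or self.n_factors < 1:
            raise ValueError("marker and factor counts must be positive")
        if not (0.0 <= self.lognormal_fraction <= 1.0):
            raise ValueError("lognormal_fraction must lie in [0, 1]")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_cohort(n_subjects, effect: CohortEffect | None = None,
                    biomarker_spec: BiomarkerSpec | None = None, seed=0):
    """Generate a cohort of :class:`SubjectRecord`.

    The marginals mirror a symptomatic small-vessel-disease population: age
    Normal(70.81, 10.61) truncated to [40, 95], 57.4% male, haematocrit
    around 0.42, log-normal PVS volumes with median near 1.6 cm^3 (whole
    brain). Mean WM BP_ND is linked to standardized log WM PVS volume through
    ``effect``; mean K_i carries no association (the null the analysis should
    report). Visual scores discretize a noisy copy of the same latent burden.
    Returns ``(records, plate_ids)``.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    if effect is None:
        effect = CohortEffect()
    if biomarker_spec is None:
        biomarker_spec = BiomarkerSpec()
    rng = np.random.default_rng(seed)

    age = _truncated_normal(rng, 70.81, 10.61, 40.0, 95.0, n_subjects)
    sex = np.where(rng.random(n_subjects) < 0.574, "male", "female")
    hct = np.clip(rng.normal(0.42, 0.035, n_subjects), 0.30, 0.55)

    # log-normal PVS volumes; z is the standardized latent WM burden
    z = rng.normal(0.0, 1.0, n_subjects)
    wm_vol = np.exp(np.log(1.06) + 0.62 * z)
    bg_vol = np.exp(rng.normal(np.log(0.33), 0.55, n_subjects))
    whole_vol = wm_vol + bg_vol  # WM + BG partition
    brain_vol = rng.normal(1150.0, 110.0, n_subjects).clip(800, 1600)

    # ordinal visual scores from a noisy copy of the latent burden
    score_latent = z + rng.normal(0.0, 0.3, n_subjects)
    cuts = np.array([-1.8, -0.6, 0.6, 1.8])
    wm_score = np.digitize(score_latent, cuts)
    bg_latent = np.log(bg_vol)
    bg_z = (bg_latent - np.log(0.33)) / 0.55 + rng.normal(0, 0.3, n_subjects)
    bg_score = np.digitize(bg_z, cuts)

    mean_bpnd = (effect.intercept + effect.slope * z
                 + rng.normal(0.0, effect.noise_sd, n_subjects))
    mean_ki = rng.normal(3e-4, 1e-4, n_subjects)

    # biomarker panel: latent factors -> markers, skew, plate effects
    spec = biomarker_spec
    loadings = rng.normal(0.0, spec.loading_sd,
                          size=(spec.n_markers, spec.n_factors))
    factors = rng.normal(0.0, 1.0, size=(n_subjects, spec.n_factors))
    panel = factors @ loadings.T + rng.normal(
        0.0, spec.noise_sd, size=(n_subjects, spec.n_markers))
    n_log = int(round(spec.lognormal_fraction * spec.n_markers))
    log_idx = rng.choice(spec.n_markers, size=n_log, replace=False)
    values = panel.copy()
    values += 8.0  # positive baseline for assay-like scales
    values[:, log_idx] = np.exp(0.8 * panel[:, log_idx])
    plate_ids = np.arange(n_subjects) // spec.plate_size
    for p in np.unique(plate_ids):
        eff = np.exp(rng.normal(0.0, spec.plate_effect_sd, spec.n_markers))
        values[plate_ids == p] *= eff[None, :]

    names = [f"BM{j + 1:03d}" for j in range(spec.n_markers)]
    records = []
    for i in range(n_subjects):
        records.append(SubjectRecord(
            id=f"S{i + 1:03d}",
            age=float(age[i]),
            sex=str(sex[i]),
            haematocrit=float(hct[i]),
            wm_pvs_score=int(wm_score[i]),
            bg_pvs_score=int(bg_score[i]),
            whole_pvs_volume_cm3=float(whole_vol[i]),
            wm_pvs_volume_cm3=float(wm_vol[i]),
            bg_pvs_volume_cm3=float(bg_vol[i]),
            brain_volume_cm3=float(brain_vol[i]),
            mean_bpnd=float(mean_bpnd[i]),
            mean_ki=float(mean_ki[i]),
            biomarkers=dict(zip(names, values[i])),
        ))
    return records, plate_ids


def cohort_frame(records) -> "pd.DataFrame":
    """Cohort records as a tidy DataFrame (one row per subject)."""
    import pandas as pd

    return pd.DataFrame([r.to_row() for r in records])


DEFAULT_LAYER_PROFILE = (1.0, 0.5, 0.25, 0.0)
PENUMBRA_LAYERS = ("PVS", "layer1", "layer2", "layer3")


def simulate_layer_cohort(n_subjects=20, effect_sd=0.3, seed=0,
                          profile=DEFAULT_LAYER_PROFILE, between_sd=1.0,
                          within_sd=0.1, baseline=-0.05):
    """Per-subject penumbra-layer means with a proximity gradient.

    Each subject's mean in layer j is
    ``baseline + b_i + effect_sd * between_sd * profile[j] + e_ij`` with
    subject intercepts ``b_i ~ N(0, between_sd)`` and measurement noise
    ``e_ij ~ N(0, within_sd)``. Because a layer mean averages thousands of
    voxels, its measurement noise is small relative to between-subject
    spread; ``within_sd`` defaults to a tenth of ``between_sd``. The decaying
    ``profile`` places the largest elevation in the layer nearest the PVS.
    Returns a long DataFrame with columns subject, layer, value.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    profile = np.asarray(profile, dtype=float)
    b = rng.normal(0.0, between_sd, n_subjects)
    rows = []
    for i in range(n_subjects):
        eps = rng.normal(0.0, within_sd, len(profile))
        vals = baseline + b[i] + effect_sd * between_sd * profile + eps
        for j, layer in enumerate(PENUMBRA_LAYERS[:len(profile)]):
            rows.append({"subject": f"S{i + 1:03d}", "layer": layer,
                         "value": vals[j]})
    return pd.DataFrame(rows)
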