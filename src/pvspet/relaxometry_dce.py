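"""Variable-flip-angle T1 mapping and Patlak permeability estimation.

The blood-brain-barrier influx rate K_i is obtained from dynamic
contrast-enhanced MRI in four steps: (i) a per-voxel T1/M0 fit to the
multi-flip-angle spoiled-gradient-echo (SPGR) baseline, (ii) conversion of
dynamic T1 changes to gadolinium concentration through the relaxivity r1,
(iii) extraction of a plasma input function from a venous (sagittal-sinus)
region with the (1 - haematocrit) correction, and (iv) Patlak graphical
analysis, whose slope is K_i (min^-1) and intercept the plasma fraction v_p.

Voxels where a fit has no physical solution propagate as NaN plus a validity
mask, never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageVolume, TimeActivityCurve, signed_cube_root

__all__ = [
    "VFASeries",
    "PatlakResult",
    "spgr_signal",
    "fit_vfa_t1",
    "dynamic_t1_from_signal",
    "concentration_from_t1",
    "extract_input_function",
    "patlak_fit",
    "patlak_map",
    "mean_ki",
]


def spgr_signal(m0, t1_ms, tr_ms, flip_deg):
    """Spoiled gradient-echo steady-state signal.

    S = M0 sin(a) (1 - E1) / (1 - E1 cos(a)),  E1 = exp(-TR / T1).
    """
    alpha = np.deg2rad(flip_deg)
    e1 = np.exp(-tr_ms / np.asarray(t1_ms, dtype=float))
    return np.asarray(m0) * np.sin(alpha) * (1.0 - e1) / (1.0 - e1 * np.cos(alpha))


@dataclass
class VFASeries:
    """SPGR volumes acquired at several flip angles with a common TR (ms)."""

    signals: list  # list[ImageVolume], one per flip angle
    flip_angles_deg: list
    tr_ms: float

    def __post_init__(self):
        if len(set(np.round(self.flip_angles_deg, 6))) < 2:
            raise ValueError("need at least 2 distinct flip angles")
        if len(self.signals) != len(self.flip_angles_deg):
            raise ValueError("one signal volume per flip angle required")
        if self.tr_ms <= 0:
            raise ValueError("TR must be positive")
        shapes = {tuple(v.shape) for v in self.signals}
        if len(shapes) != 1:
            raise ValueError("flip-angle volumes must share a grid")

    def stack(self) -> np.ndarray:
        return np.stack([v.data for v in self.signals], axis=-1)


@dataclass
class PatlakResult:
    """Patlak fit: influx rate K_i (min^-1), plasma fraction v_p, fit R^2 and
    the number of phases used."""

    ki: float
    vp: float
    r_squared: float
    n_points_used: int


def fit_vfa_t1(vfa: VFASeries, max_rel_residual=2e-3):
    """Per-voxel (T1, M0) by linearising the SPGR equation.

    Regressing y = S/sin(a) on x = S/tan(a) gives slope E1 = exp(-TR/T1) and
    intercept M0 (1 - E1). Voxels whose slope falls outside (0, 1) have no
    physical solution and are returned as NaN, as are voxels whose
    linearised points do not actually lie on a line (relative RMS lack of
    fit above ``max_rel_residual``) — e.g. a signal identical at every
    angle, which no SPGR parameter pair can produce. The boolean validity
    mask is the third element of the returned tuple.

    Returns ``(t1_map, m0_map, valid)`` with T1 in ms.
    """
    angles = np.deg2rad(np.asarray(vfa.flip_angles_deg, dtype=float))
    sig = vfa.stack()  # (..., n_angles)
    if not np.any(sig > 0):
        raise ValueError("all VFA signals are zero")

    y = sig / np.sin(angles)
    x = sig / np.tan(angles)
    n = len(angles)
    sx = x.sum(axis=-1)
    sy = y.sum(axis=-1)
    sxx = (x * x).sum(axis=-1)
    sxy = (x * y).sum(axis=-1)
    denom = n * sxx - sx * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (n * sxy - sx * sy) / denom
        intercept = (sy - slope * sx) / n

    fitted = slope[..., None] * x + intercept[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_rms = np.sqrt(((y - fitted) ** 2).mean(axis=-1)
                          / (y ** 2).mean(axis=-1))
    valid = (np.isfinite(slope) & (slope > 0) & (slope < 1)
             & (np.abs(denom) > 1e-30) & np.isfinite(intercept)
             & (intercept > 0) & (rel_rms <= max_rel_residual))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(valid, -vfa.tr_ms / np.log(
            np.where(valid, slope, 0.5)), np.nan)
        m0 = np.where(valid, intercept / (1.0 - np.where(valid, slope, 0.5)),
                      np.nan)

    affine = vfa.signals[0].affine
    return (ImageVolume(t1, affine), ImageVolume(m0, affine),
            ImageVolume(valid, affine))


def dynamic_t1_from_signal(signal, m0_map, tr_ms, flip_deg):
    """Invert the SPGR equation for T1 at a single flip angle, given M0.

    Used for the dynamic phases, which are acquired at one angle: with
    m = M0 sin(a), E1 = (m - S) / (m - S cos(a)) and T1 = -TR / ln(E1).
    Non-physical voxels (E1 outside (0, 1)) become NaN.
    """
    alpha = np.deg2rad(flip_deg)
    s = np.asarray(signal, dtype=float)
    m0 = m0_map.data if isinstance(m0_map, ImageVolume) else np.asarray(m0_map)
    m = m0 * np.sin(alpha)
    if s.ndim == m.ndim + 1:
        m = m[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (m - s) / (m - s * np.cos(alpha))
        valid = np.isfinite(e1) & (e1 > 0) & (e1 < 1)
        t1 = np.where(valid, -tr_ms / np.log(np.where(valid, e1, 0.5)), np.nan)
    return t1


def concentration_from_t1(t1_t_ms, t1_0_ms, r1_relaxivity):
    """Gadolinium concentration from T1 shortening.

    C = (1/T1(t) - 1/T1_0) / r1 with T1 in ms converted to rates in s^-1 and
    r1 in L mmol^-1 s^-1, giving C in mmol/L. ``t1_t_ms`` may carry a
    trailing phase axis against a 3D baseline map.
    """
    if r1_relaxivity <= 0:
        raise ValueError("relaxivity r1 must be positive")
    t1_t = np.asarray(t1_t_ms, dtype=float)
    t1_0 = t1_0_ms.data if isinstance(t1_0_ms, ImageVolume) \
        else np.asarray(t1_0_ms, dtype=float)
    if t1_t.ndim == t1_0.ndim + 1:
        t1_0 = t1_0[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        conc = (1000.0 / t1_t - 1000.0 / t1_0) / r1_relaxivity
    return conc


def extract_input_function(conc_series, times, sinus_mask, haematocrit=0.45
                           ) -> TimeActivityCurve:
    """Plasma input function from a venous blood region.

    The mean whole-blood concentration over the sinus mask is divided by
    (1 - haematocrit) to give the plasma concentration the Patlak model
    requires.
    """
    if not (0.0 < haematocrit < 1.0):
        raise ValueError("haematocrit must lie in (0, 1)")
    mask = sinus_mask.astype_bool() if isinstance(sinus_mask, ImageVolume) \
        else np.asarray(sinus_mask, dtype=bool)
    if not mask.any():
        raise ValueError("sinus mask is empty")
    conc = np.asarray(conc_series, dtype=float)
    blood = np.nanmean(conc[mask], axis=0)
    return TimeActivityCurve(np.asarray(times, dtype=float),
                             blood / (1.0 - haematocrit),
                             kind="plasma_input")


def _patlak_xy(tissue, plasma, times, t_start):
    """Patlak coordinates and the usable-phase selector."""
    cp = np.asarray(plasma, dtype=float)
    ct = np.asarray(tissue, dtype=float)
    t = np.asarray(times, dtype=float)
    cp_int = np.concatenate([[0.0], np.cumsum(
        0.5 * (cp[1:] + cp[:-1]) * np.diff(t))])
    use = (cp > 0) & (t >= t_start) & np.isfinite(ct)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(use, cp_int / cp, np.nan)
        y = np.where(use, ct / cp, np.nan)
    return x, y, use


def patlak_fit(tissue_conc: TimeActivityCurve, plasma: TimeActivityCurve,
               t_start=0.0) -> PatlakResult:
    """Patlak graphical analysis of one tissue curve.

    Ordinary least squares of y = C_t/C_p against x = int_0^t C_p / C_p
    (trapezoidal plasma integral) over phases with C_p > 0 and t >= t_start.
    Slope is K_i (min^-1), intercept v_p.
    """
    if not np.allclose(tissue_conc.times, plasma.times):
        raise ValueError("tissue and plasma curves must share the time grid")
    x, y, use = _patlak_xy(tissue_conc.values, plasma.values,
                           plasma.times, t_start)
    n_use = int(use.sum())
    if n_use < 3:
        raise ValueError(
            f"only {n_use} usable phases (C_p > 0 and t >= t_start); "
            "need at least 3")
    xs, ys = x[use], y[use]
    A = np.column_stack([xs, np.ones_like(xs)])
    coef, *_ = np.linalg.lstsq(A, ys, rcond=None)
    fitted = A @ coef
    ss_res = float(((ys - fitted) ** 2).sum())
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return PatlakResult(ki=float(coef[0]), vp=float(coef[1]),
                        r_squared=r2, n_points_used=n_use)


def patlak_map(conc_series, times, plasma: TimeActivityCurve, brain_mask,
               t_start=0.0):
    """Voxelwise Patlak fit inside a mask.

    Returns ``(ki_map, vp_map, valid)``; voxels outside the mask or with a
    degenerate design are NaN. The design matrix is shared across voxels, so
    the fit is a single batched least-squares solve.
    """
    mask = brain_mask.astype_bool() if isinstance(brain_mask, ImageVolume) \
        else np.asarray(brain_mask, dtype=bool)
    affine = brain_mask.affine if isinstance(brain_mask, ImageVolume) \
        else np.eye(4)
    conc = np.asarray(conc_series, dtype=float)
    t = np.asarray(times, dtype=float)
    cp = plasma.values
    cp_int = np.concatenate([[0.0], np.cumsum(
        0.5 * (cp[1:] + cp[:-1]) * np.diff(t))])
    use = (cp > 0) & (t >= t_start)
    if use.sum() < 3:
        raise ValueError("fewer than 3 usable phases for the Patlak fit")
    x = cp_int[use] / cp[use]
    A = np.column_stack([x, np.ones_like(x)])
    Y = conc[mask][:, use] / cp[use]
    finite = np.isfinite(Y).all(axis=1)
    coef = np.full((Y.shape[0], 2), np.nan)
    if finite.any():
        sol, *_ = np.linalg.lstsq(A, Y[finite].T, rcond=None)
        coef[finite] = sol.T

    ki = np.full(mask.shape, np.nan)
    vp = np.full(mask.shape, np.nan)
    ki[mask] = coef[:, 0]
    vp[mask] = coef[:, 1]
    valid = np.zeros(mask.shape, dtype=bool)
    valid[mask] = finite
    return (ImageVolume(ki, affine), ImageVolume(vp, affine),
            ImageVolume(valid, affine))


def mean_ki(ki_map, region_mask):
    """Regional mean K_i over valid (finite) voxels.

    Returns ``(mean, signed_cube_root(mean))``; the cube-root value is the
    normality transform used by the association stage, signed so that
    negative regional means stay defined.
    """
    data = ki_map.data if isinstance(ki_map, ImageVolume) \
        else np.asarray(ki_map, dtype=float)
    mask = region_mask.astype_bool() if isinstance(region_mask, ImageVolume) \
        else np.asarray(region_mask, dtype=bool)
    if not mask.any():
        raise ValueError("region mask is empty")
    vals = data[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid voxels in region")
    m = float(vals.mean())
    return m, signed_cube_root(m)
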