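"""Binding-potential mapping with a basis-function simplified reference
tissue model (SRTM), including correction for vascular binding.

The SRTM describes a tissue time-activity curve through a reference region:

    C_t(t) = theta1 * C_r(t) + theta2 * [C_r conv exp(-theta3 t)](t)

with R1 = theta1 (delivery ratio), k2 = theta2 + R1 * theta3 (reference
efflux, min^-1) and BP_ND = k2 / theta3 - 1. The fit scans a fixed grid of
theta3 values; for each, the remaining coefficients solve a linear
least-squares problem weighted by frame duration, and the grid point with
the smallest residual wins. Vascular binding (tracer in blood and
endothelium) is handled by adding the whole-blood curve as one more linear
regressor, so each basis subproblem stays linear.

BP_ND may legitimately be negative when the target region binds less tracer
than the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import DynamicImage, ImageVolume, TimeActivityCurve, signed_cube_root

__all__ = [
    "SRTMBasis",
    "SRTMResult",
    "smooth_gaussian",
    "extract_vascular_curve",
    "make_srtm_basis",
    "srtm_fit",
    "bpnd_map",
    "mean_bpnd",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth_gaussian(dyn: DynamicImage, fwhm_mm: float) -> DynamicImage:
    """Per-frame 3D Gaussian smoothing, applied before BP_ND mapping.

    sigma = fwhm / (2 sqrt(2 ln 2)) in mm, converted to voxels per axis via
    the image spacing. ``fwhm_mm = 0`` returns the input unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return dyn
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / dyn.spacing
    out = np.empty_like(np.asarray(dyn.data, dtype=float))
    for k in range(dyn.n_frames):
        out[..., k] = ndimage.gaussian_filter(
            np.asarray(dyn.data[..., k], dtype=float), sigma=sigma_vox)
    return DynamicImage(out, dyn.frame_mid_times.copy(),
                        dyn.frame_durations.copy(), dyn.affine)


def extract_vascular_curve(dyn: DynamicImage, brain_mask, n_voxels=10,
                           n_frames=5) -> TimeActivityCurve:
    """Whole-blood curve from the early-peaking voxels.

    Voxels inside the mask are ranked by summed activity over the first
    ``n_frames`` frames; the ``n_voxels`` hottest are averaged across the
    full time course. Ties are broken by flat voxel index, so the output is
    deterministic.
    """
    mask = brain_mask.astype_bool() if isinstance(brain_mask, ImageVolume) \
        else np.asarray(brain_mask, dtype=bool)
    n_in_mask = int(mask.sum())
    if n_in_mask < n_voxels:
        raise ValueError(
            f"mask has {n_in_mask} voxels, fewer than n_voxels={n_voxels}")
    tacs = dyn.data[mask]  # (n_in_mask, n_frames) in flat-index order
    early = tacs[:, :n_frames].sum(axis=1)
    # stable sort on -early keeps flat-index order among ties
    order = np.argsort(-early, kind="stable")[:n_voxels]
    curve = tacs[order].mean(axis=0)
    return TimeActivityCurve(dyn.frame_mid_times, curve, kind="vascular")


@dataclass
class SRTMBasis:
    """Precomputed exponential-convolution basis on the frame time grid."""

    theta3_grid: np.ndarray          # (n_basis,), min^-1, increasing
    basis_curves: np.ndarray         # (n_basis, n_frames)
    times: np.ndarray                # frame mid-times, minutes
    reference: np.ndarray            # reference curve on the same grid

    def __post_init__(self):
        self.theta3_grid = np.asarray(self.theta3_grid, dtype=float)
        if self.theta3_grid.size == 0:
            raise ValueError("theta3 grid is empty")
        if np.any(self.theta3_grid <= 0):
            raise ValueError("all theta3 values must be positive")
        if np.any(np.diff(self.theta3_grid) <= 0):
            raise ValueError("theta3 grid must be strictly increasing")
        if self.basis_curves.shape != (len(self.theta3_grid), len(self.times)):
            raise ValueError("one basis curve per grid point required")


@dataclass
class SRTMResult:
    """SRTM parameters for one time-activity curve."""

    r1: float
    k2: float
    bp_nd: float
    vb: float | None
    theta3: float
    rss: float


def _conv_exp_piecewise_linear(times, values, thetas):
    """Exact convolution of a piecewise-linear curve with exp(-theta t).

    The curve is taken linear between samples and linear from (0, 0) to the
    first sample — frame durations vary widely, so quadrature on the sample
    grid would be inaccurate for the early, fast-changing frames.
    Returns an array (n_theta, n_times).
    """
    t = np.concatenate([[0.0], np.asarray(times, dtype=float)])
    c = np.concatenate([[0.0], np.asarray(values, dtype=float)])
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    n_t = len(times)
    out = np.zeros((len(thetas), n_t))
    acc = np.zeros(len(thetas))
    for k in range(1, len(t)):
        dt = t[k] - t[k - 1]
        c0 = c[k - 1]
        s = (c[k] - c[k - 1]) / dt
        e = np.exp(-thetas * dt)
        seg = (c0 * (1.0 - e) / thetas
               + s * (dt * (1.0 - e) / thetas
                      - (1.0 - e * (1.0 + thetas * dt)) / thetas ** 2))
        acc = acc * e + seg
        out[:, k - 1] = acc
    return out


def make_srtm_basis(reference: TimeActivityCurve, theta3_min=0.006,
                    theta3_max=0.6, n_basis=64) -> SRTMBasis:
    """Log-spaced theta3 grid with exact piecewise-linear basis curves."""
    if not np.any(reference.values != 0):
        raise ValueError("reference curve is identically zero")
    grid = np.geomspace(theta3_min, theta3_max, n_basis)
    curves = _conv_exp_piecewise_linear(reference.times, reference.values,
                                        grid)
    return SRTMBasis(grid, curves, np.asarray(reference.times, dtype=float),
                     np.asarray(reference.values, dtype=float))


def _batched_srtm(Y, basis: SRTMBasis, durations, vascular=None):
    """Fit SRTM to many TACs at once.

    Y: (n_frames, n_vox). Returns dict of per-voxel parameter arrays.
    """
    n_frames, n_vox = Y.shape
    w = np.sqrt(np.asarray(durations, dtype=float))
    Yw = Y * w[:, None]
    ref = basis.reference
    has_vb = vascular is not None
    p = 3 if has_vb else 2

    best_rss = np.full(n_vox, np.inf)
    best_coef = np.zeros((n_vox, p))
    best_idx = np.zeros(n_vox, dtype=int)

    cols = [ref, None] + ([np.asarray(vascular, dtype=float)] if has_vb else [])
    for i, theta3 in enumerate(basis.theta3_grid):
        cols[1] = basis.basis_curves[i]
        A = np.column_stack(cols) * w[:, None]
        coef, *_ = np.linalg.lstsq(A, Yw, rcond=None)
        resid = Yw - A @ coef
        rss = (resid ** 2).sum(axis=0)
        better = rss < best_rss
        best_rss[better] = rss[better]
        best_coef[better] = coef.T[better]
        best_idx[better] = i

    theta1 = best_coef[:, 0]
    theta2 = best_coef[:, 1]
    theta3 = basis.theta3_grid[best_idx]
    k2 = theta2 + theta1 * theta3
    with np.errstate(divide="ignore", invalid="ignore"):
        bp = k2 / theta3 - 1.0
    return {
        "r1": theta1,
        "k2": k2,
        "bp_nd": bp,
        "vb": best_coef[:, 2] if has_vb else None,
        "theta3": theta3,
        "rss": best_rss,
    }


def srtm_fit(tac: TimeActivityCurve, reference: TimeActivityCurve,
             basis: SRTMBasis | None = None,
             vascular: TimeActivityCurve | None = None,
             frame_durations=None) -> SRTMResult:
    """Fit the SRTM (optionally with the vascular regressor) to one curve."""
    if not np.allclose(tac.times, reference.times):
        raise ValueError("tissue and reference curves must share the grid")
    if vascular is not None and not np.allclose(tac.times, vascular.times):
        raise ValueError("vascular curve must share the frame grid")
    if basis is None:
        basis = make_srtm_basis(reference)
    if frame_durations is None:
        frame_durations = np.ones(len(tac))
    vb_curve = vascular.values if vascular is not None else None
    res = _batched_srtm(tac.values[:, None], basis,
                        frame_durations, vb_curve)
    return SRTMResult(
        r1=float(res["r1"][0]),
        k2=float(res["k2"][0]),
        bp_nd=float(res["bp_nd"][0]),
        vb=float(res["vb"][0]) if res["vb"] is not None else None,
        theta3=float(res["theta3"][0]),
        rss=float(res["rss"][0]),
    )


def bpnd_map(dyn: DynamicImage, reference: TimeActivityCurve,
             basis: SRTMBasis | None = None,
             vascular: TimeActivityCurve | None = None, brain_mask=None):
    """Voxelwise SRTM fit inside a mask.

    Returns a dict of ImageVolumes: ``bp_nd``, ``r1``, ``k2``, ``vb`` (when a
    vascular curve is supplied) and ``valid``. Voxels outside the mask are
    NaN.
    """
    if basis is None:
        basis = make_srtm_basis(reference)
    if brain_mask is None:
        mask = np.ones(dyn.data.shape[:3], dtype=bool)
    else:
        mask = brain_mask.astype_bool() if isinstance(brain_mask, ImageVolume) \
            else np.asarray(brain_mask, dtype=bool)
    Y = np.asarray(dyn.data[mask], dtype=float).T  # (n_frames, n_vox)
    vb_curve = vascular.values if vascular is not None else None
    res = _batched_srtm(Y, basis, dyn.frame_durations, vb_curve)

    out = {}
    for key in ("bp_nd", "r1", "k2", "vb"):
        if res[key] is None:
            continue
        vol = np.full(mask.shape, np.nan)
        vol[mask] = res[key]
        out[key] = ImageVolume(vol, dyn.affine)
    valid = np.zeros(mask.shape, dtype=bool)
    valid[mask] = np.isfinite(res["bp_nd"])
    out["valid"] = ImageVolume(valid, dyn.affine)
    return out


def mean_bpnd(bpnd_vol, region_mask):
    """Regional mean BP_ND over valid voxels, plus its signed cube root.

    Negative regional means are expected when the region binds less than the
    reference tissue; the signed cube root keeps the normality transform
    defined there.
    """
    data = bpnd_vol.data if isinstance(bpnd_vol, ImageVolume) \
        else np.asarray(bpnd_vol, dtype=float)
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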