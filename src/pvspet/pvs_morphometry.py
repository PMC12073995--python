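"""Perivascular-space morphometry: count-based visual rating, regional
volumes with brain-volume normalization, white-matter mask erosion and the
concentric "penumbra" shells at one, two and three voxels from the PVS.

All morphology acts in voxel space. Dilation "in all directions" uses the
full 26-connected 3x3x3 structuring element (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .core import ImageVolume

__all__ = [
    "PVSMetrics",
    "PenumbraShells",
    "visual_rating",
    "pvs_volumes",
    "erode_mask",
    "build_penumbra",
    "shell_means",
    "LAYER_NAMES",
]

# visual rating categories: 0 no PVS, 1 mild (1-10), 2 moderate (11-20),
# 3 frequent (21-40), 4 severe (>40) PVS in the busiest slice
RATING_BINS = (0, 10, 20, 40)

LAYER_NAMES = ("PVS", "layer1", "layer2", "layer3")


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, ImageVolume):
        return mask.astype_bool()
    return np.asarray(mask, dtype=bool)


@dataclass
class PVSMetrics:
    """Regional PVS volumes (cm^3) and normalized log volumes.

    ``normalized_log`` entries are ln(volume / brain volume); regions with
    zero PVS volume are recorded as None (excluded from log-scale analyses)
    rather than propagated as -inf.
    """

    whole_volume_cm3: float
    wm_volume_cm3: float
    bg_volume_cm3: float
    brain_volume_cm3: float
    normalized_log: dict = field(default_factory=dict)


@dataclass
class PenumbraShells:
    """Ordered, pairwise-disjoint shells around a PVS mask.

    ``shells[k]`` is the set of voxels first reached by the (k+1)-th dilation
    of the PVS mask, intersected with the restriction (white-matter) mask.
    """

    pvs_layer: np.ndarray
    shells: list
    restriction_mask: np.ndarray

    def layer_masks(self):
        """Mapping of layer name -> mask, innermost first."""
        out = {"PVS": self.pvs_layer}
        for k, shell in enumerate(self.shells, start=1):
            out[f"layer{k}"] = shell
        return out


def score_from_count(max_slice_count: int) -> int:
    """Map the busiest-slice PVS count to the 0-4 rating category."""
    if max_slice_count < 0:
        raise ValueError("count must be non-negative")
    return int(np.searchsorted(RATING_BINS, max_slice_count))


def visual_rating(pvs_mask, region_mask, axis=2):
    """Automated count-based PVS rating.

    Counts 2D connected components (8-connectivity) of the PVS mask within
    the region on every slice along ``axis``, takes the maximum slice count
    N, and maps it to the ordinal scale 0 (N=0), 1 (1-10), 2 (11-20),
    3 (21-40), 4 (>40). Returns ``(score, per_slice_counts)``.
    """
    pvs = _as_bool(pvs_mask)
    region = _as_bool(region_mask)
    if pvs.shape != region.shape:
        raise ValueError("PVS and region masks must share a grid")
    if not region.any():
        raise ValueError("region mask is empty")
    joint = pvs & region
    counts = []
    for k in range(joint.shape[axis]):
        sl = np.take(joint, k, axis=axis)
        counts.append(int(measure.label(sl, connectivity=2).max()))
    counts = np.asarray(counts)
    return score_from_count(int(counts.max())), counts


def pvs_volumes(pvs_mask, wm_mask, bg_mask, brain_volume_cm3, spacing
                ) -> PVSMetrics:
    """Regional PVS volumes and brain-volume-normalized log volumes.

    Volume is voxel count times voxel volume, converted mm^3 -> cm^3; the
    whole-PVS volume is taken within WM plus BG. Normalized log volume is
    ln(volume / brain volume); a zero regional volume yields None.
    """
    if brain_volume_cm3 <= 0:
        raise ValueError("brain volume must be positive")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    pvs = _as_bool(pvs_mask)
    wm = _as_bool(wm_mask)
    bg = _as_bool(bg_mask)
    vox_cm3 = float(np.prod(spacing)) / 1000.0

    wm_vol = float((pvs & wm).sum()) * vox_cm3
    bg_vol = float((pvs & bg).sum()) * vox_cm3
    whole_vol = float((pvs & (wm | bg)).sum()) * vox_cm3

    normalized_log = {}
    for name, vol in (("whole", whole_vol), ("wm", wm_vol), ("bg", bg_vol)):
        normalized_log[name] = (
            float(np.log(vol / brain_volume_cm3)) if vol > 0 else None)
    return PVSMetrics(whole_vol, wm_vol, bg_vol, float(brain_volume_cm3),
                      normalized_log)


def _ball_structure(radius_mm, spacing):
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    half = np.floor(radius_mm / spacing).astype(int)
    grids = np.indices(tuple(2 * half + 1)).astype(float)
    dist2 = sum(((grids[i] - half[i]) * spacing[i]) ** 2 for i in range(3))
    return dist2 <= radius_mm ** 2 + 1e-9


def erode_mask(mask, distance_mm, spacing=None):
    """Morphological erosion with a spherical element of the given world
    radius (mm). Used to shrink the white-matter mask away from ventricular
    and grey-matter boundaries. ``distance_mm = 0`` is the identity.
    """
    if distance_mm < 0:
        raise ValueError("erosion distance must be non-negative")
    if spacing is None:
        spacing = mask.spacing if isinstance(mask, ImageVolume) else (1, 1, 1)
    m = _as_bool(mask)
    if distance_mm == 0:
        out = m.copy()
    else:
        structure = _ball_structure(distance_mm, spacing)
        out = ndimage.binary_erosion(m, structure=structure)
        if m.any() and not out.any():
            import warnings

            warnings.warn("erosion removed the entire mask", stacklevel=2)
    if isinstance(mask, ImageVolume):
        return ImageVolume(out, mask.affine)
    return out


def build_penumbra(pvs_mask, wm_mask, n_shells=3, connectivity=3
                   ) -> PenumbraShells:
    """Concentric shells around the PVS, restricted to white matter.

    D_k is the binary dilation of the PVS mask by k iterations of the
    3x3x3 structuring element (``connectivity=3`` -> the full 26-neighbour
    cube; 1 -> the 6-connected cross). Shell k is (D_k minus D_{k-1})
    intersected with the white-matter mask, with D_0 the PVS mask itself.
    """
    pvs = _as_bool(pvs_mask)
    wm = _as_bool(wm_mask)
    if pvs.shape != wm.shape:
        raise ValueError("PVS and WM masks must share a grid")
    if not pvs.any():
        raise ValueError("PVS mask is empty")
    structure = ndimage.generate_binary_structure(3, connectivity)
    shells = []
    prev = pvs
    for _ in range(n_shells):
        dil = ndimage.binary_dilation(prev, structure=structure)
        shells.append((dil & ~prev) & wm)
        prev = dil
    return PenumbraShells(pvs & wm, shells, wm)


def shell_means(shells: PenumbraShells, scalar_map) -> pd.DataFrame:
    """Per-layer summary of a scalar map (mean BP_ND or mean K_i).

    Returns a table with columns layer, n_voxels, mean, sd over valid
    (finite) voxels; layers with no valid voxels get NaN mean and sd.
    """
    data = scalar_map.data if isinstance(scalar_map, ImageVolume) \
        else np.asarray(scalar_map, dtype=float)
    rows = []
    for layer, mask in shells.layer_masks().items():
        vals = data[mask]
        vals = vals[np.isfinite(vals)]
        rows.append({
            "layer": layer,
            "n_voxels": int(vals.size),
            "mean": float(vals.mean()) if vals.size else np.nan,
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
        })
    return pd.DataFrame(rows)
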