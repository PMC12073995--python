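"""NIfTI and CSV input/output.

Volumes travel as NIfTI-1 through :mod:`nibabel`. Per-frame timing for
dynamic series lives in a sidecar CSV with columns ``start_min`` and
``duration_min`` (NIfTI headers carry no per-frame schedule); frame mid-times
are ``start + duration / 2``.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd

from .core import DynamicImage, ImageVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_dynamic",
    "write_dynamic",
    "read_timing",
    "write_timing",
]

TIMING_COLUMNS = ("start_min", "duration_min")


def _load_nifti(path):
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # corrupt header, wrong magic, ...
        raise ValueError(f"could not read {path} as NIfTI: {exc}") from exc
    return img


def read_volume(path) -> ImageVolume:
    """Read a 3D NIfTI volume."""
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got {data.ndim}D "
            f"with shape {data.shape} (use read_dynamic for 4D series)"
        )
    return ImageVolume(data, np.asarray(img.affine))


def write_volume(vol: ImageVolume, path) -> None:
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, vol.affine), path)


def read_timing(timing_path) -> pd.DataFrame:
    tab = pd.read_csv(timing_path)
    missing = [c for c in TIMING_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(
            f"timing table {timing_path} lacks required column(s): {missing}"
        )
    return tab


def write_timing(frame_starts, frame_durations, path) -> None:
    pd.DataFrame(
        {"start_min": np.asarray(frame_starts), "duration_min": np.asarray(frame_durations)}
    ).to_csv(path, index=False)


def read_dynamic(path, timing_path) -> DynamicImage:
    """Read a 4D NIfTI series plus its sidecar timing CSV."""
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(
            f"{path}: expected a 4D dynamic series, got {data.ndim}D"
        )
    timing = read_timing(timing_path)
    if len(timing) != data.shape[3]:
        raise ValueError(
            f"frame count mismatch: image has {data.shape[3]} frames but the "
            f"timing table has {len(timing)} rows"
        )
    starts = timing["start_min"].to_numpy(dtype=float)
    durations = timing["duration_min"].to_numpy(dtype=float)
    return DynamicImage(
        data, starts + durations / 2.0, durations, np.asarray(img.affine)
    )


def write_dynamic(dyn: DynamicImage, path, timing_path=None) -> None:
    nib.save(nib.Nifti1Image(dyn.data, dyn.affine), path)
    if timing_path is not None:
        starts = dyn.frame_mid_times - dyn.frame_durations / 2.0
        write_timing(starts, dyn.frame_durations, timing_path)
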