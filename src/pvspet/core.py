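"""Shared data model for the perivascular-space PET-MRI pipeline.

All internal units are fixed by convention: times in minutes, activities in
kBq/ml, gadolinium concentrations in mmol/L, T1 in milliseconds, influx rates
(K_i) in min^-1, voxel spacing in mm. Volumes carry a 4x4 affine mapping
0-based voxel indices to world coordinates; morphological operations act in
voxel space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageVolume",
    "DynamicImage",
    "TimeActivityCurve",
    "SubjectRecord",
    "signed_cube_root",
]


def signed_cube_root(x):
    """Signed cube root, sign(x) * |x|**(1/3).

    Used to symmetrise kinetic summaries (mean BP_ND, mean K_i) which may be
    negative relative to a reference region, where a plain power would be
    undefined.
    """
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.abs(x) ** (1.0 / 3.0)
    return float(out) if out.ndim == 0 else out


def _spacing_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


@dataclass
class ImageVolume:
    """A 3D scalar field with voxel geometry.

    Carrier for T1 maps, K_i maps, BP_ND maps and binary/label masks. NaN is
    permitted only where an accompanying validity mask marks voxels undefined.
    """

    data: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"ImageVolume requires a 3D array, got {self.data.ndim}D "
                f"with shape {self.data.shape}"
            )
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive along every axis")

    @classmethod
    def from_spacing(cls, data, spacing) -> "ImageVolume":
        spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
        affine = np.diag([*spacing, 1.0])
        return cls(np.asarray(data), affine)

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return _spacing_from_affine(self.affine)

    @property
    def shape(self):
        return self.data.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def astype_bool(self) -> np.ndarray:
        return self.data.astype(bool)


@dataclass
class DynamicImage:
    """A 4D dynamic series (x, y, z, frame) with per-frame timing in minutes."""

    data: np.ndarray
    frame_mid_times: np.ndarray
    frame_durations: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"DynamicImage requires a 4D array, got {self.data.ndim}D"
            )
        self.frame_mid_times = np.asarray(self.frame_mid_times, dtype=float)
        self.frame_durations = np.asarray(self.frame_durations, dtype=float)
        n = self.data.shape[3]
        if len(self.frame_mid_times) != n or len(self.frame_durations) != n:
            raise ValueError(
                f"frame timing length ({len(self.frame_mid_times)} mid-times, "
                f"{len(self.frame_durations)} durations) does not match the "
                f"number of frames ({n})"
            )
        if np.any(np.diff(self.frame_mid_times) <= 0):
            raise ValueError("frame mid-times must be strictly increasing")
        if np.any(self.frame_durations < 0):
            raise ValueError("frame durations must be non-negative")
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def spacing(self) -> np.ndarray:
        return _spacing_from_affine(self.affine)

    def frame(self, k: int) -> ImageVolume:
        return ImageVolume(self.data[..., k], self.affine)

    def voxel_tac(self, index) -> "TimeActivityCurve":
        i, j, k = index
        return TimeActivityCurve(
            self.frame_mid_times, self.data[i, j, k, :], kind="tissue"
        )


@dataclass
class TimeActivityCurve:
    """Paired (time, value) samples for reference, vascular, plasma-input or
    tissue curves. Times in minutes."""

    times: np.ndarray
    values: np.ndarray
    kind: str = "tissue"

    _KINDS = ("reference", "vascular", "plasma_input", "tissue")

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class SubjectRecord:
    """One cohort row: demographics, haematocrit, PVS metrics, regional
    kinetic means and the blood-biomarker panel."""

    id: str
    age: float
    sex: str  # "male" | "female"
    haematocrit: float = 0.45
    wm_pvs_score: int | None = None
    bg_pvs_score: int | None = None
    whole_pvs_volume_cm3: float | None = None
    wm_pvs_volume_cm3: float | None = None
    bg_pvs_volume_cm3: float | None = None
    brain_volume_cm3: float | None = None
    mean_bpnd: float | None = None
    mean_ki: float | None = None
    biomarkers: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if not (0.0 < self.haematocrit < 1.0):
            raise ValueError("haematocrit must lie in (0, 1)")
        for score in (self.wm_pvs_score, self.bg_pvs_score):
            if score is not None and score not in (0, 1, 2, 3, 4):
                raise ValueError("PVS visual scores must be integers in 0..4")
        for vol in (
            self.whole_pvs_volume_cm3,
            self.wm_pvs_volume_cm3,
            self.bg_pvs_volume_cm3,
            self.brain_volume_cm3,
        ):
            if vol is not None and vol < 0:
                raise ValueError("volumes must be non-negative")

    def to_row(self) -> dict:
        row = {
            "id": self.id,
            "age": self.age,
            "sex": self.sex,
            "haematocrit": self.haematocrit,
            "wm_pvs_score": self.wm_pvs_score,
            "bg_pvs_score": self.bg_pvs_score,
            "whole_pvs_volume_cm3": self.whole_pvs_volume_cm3,
            "wm_pvs_volume_cm3": self.wm_pvs_volume_cm3,
            "bg_pvs_volume_cm3": self.bg_pvs_volume_cm3,
            "brain_volume_cm3": self.brain_volume_cm3,
            "mean_bpnd": self.mean_bpnd,
            "mean_ki": self.mean_ki,
        }
        row.update(self.biomarkers)
        return row
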