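"""Preprocessing chain and NCC (normalized correlation coefficient) series.

The morphodynamics readout is the Pearson correlation of pixel intensities
between the frame at the start of imaging and the frame at each later time
point, computed after a fixed preprocessing chain:

    medial z-slice -> 3x3 median filter -> percentile normalization

A value near 1 means the vacuole morphology is unchanged relative to the
first frame; lower values indicate larger morphological change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

__all__ = [
    "FrameStack",
    "NCCSeries",
    "DegenerateFrameWarning",
    "select_medial_slice",
    "median_filter3",
    "normalize_percentile",
    "ncc",
    "ncc_series",
    "preprocess_stack",
]


class DegenerateFrameWarning(UserWarning):
    """A frame had zero intensity variance (or a degenerate histogram)."""


@dataclass
class FrameStack:
    """Ordered sequence of 2-D intensity frames with time metadata.

    Parameters
    ----------
    frames:
        Array of shape ``(T, H, W)`` with nonnegative intensities, or
        ``(T, Z, H, W)`` when each time point carries a z-stack.
    frame_interval_s:
        Time between consecutive frames in seconds.
    z_slices_per_timepoint:
        Number of z-slices acquired per time point (1, 3, or 5).
    """

    frames: np.ndarray
    frame_interval_s: float = 10.0
    z_slices_per_timepoint: int = 1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError(
                f"frames must be (T,H,W) or (T,Z,H,W); got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise ValueError("a FrameStack needs at least 2 time points")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.frames.ndim == 4:
            if self.frames.shape[1] != self.z_slices_per_timepoint:
                raise ValueError(
                    "z_slices_per_timepoint does not match the frames array"
                )
        elif self.z_slices_per_timepoint != 1:
            raise ValueError("3-D frames array implies one z-slice per time point")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * float(self.frame_interval_s)

    @property
    def medial_index(self) -> int:
        """Index of the medial z-slice (second of three, third of five)."""
        return _medial_index(self.z_slices_per_timepoint)


@dataclass
class NCCSeries:
    """Per-cell time series of NCC values against the first frame."""

    cell_id: str
    condition: str
    times_s: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape:
            raise ValueError("times_s and values must have the same length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (np.any(finite < -1 - 1e-9) or np.any(finite > 1 + 1e-9)):
            raise ValueError("NCC values must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "condition": self.condition,
                "time_s": self.times_s,
                "ncc": self.values,
            }
        )


def _medial_index(n_slices: int) -> int:
    if n_slices == 1:
        return 0
    if n_slices == 3:
        return 1
    if n_slices == 5:
        return 2
    raise ValueError(f"z-stack must have 1, 3, or 5 slices; got {n_slices}")


def select_medial_slice(zstack: np.ndarray) -> np.ndarray:
    """Pick the medial z-slice from a per-timepoint stack.

    Accepts a single ``(Z, H, W)`` stack or a time series ``(T, Z, H, W)``;
    a 2-D array is treated as a single slice and returned unchanged.
    """
    zstack = np.asarray(zstack)
    if zstack.ndim == 2:
        return zstack
    if zstack.ndim == 3:
        return zstack[_medial_index(zstack.shape[0])]
    if zstack.ndim == 4:
        return zstack[:, _medial_index(zstack.shape[1])]
    raise ValueError(f"expected 2-, 3-, or 4-D array; got {zstack.ndim}-D")


def median_filter3(frame: np.ndarray) -> np.ndarray:
    """3x3 median filter with reflection padding at the borders."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or min(frame.shape) < 3:
        raise ValueError("frame must be 2-D with both sides >= 3")
    return median_filter(frame, size=3, mode="reflect")


def normalize_percentile(frame: np.ndarray, p: float = 97.0) -> np.ndarray:
    """Rescale so the p-th intensity percentile becomes the dynamic-range max.

    Intensities at or above the percentile saturate at 255; below it the
    mapping is linear from ``[min, percentile]`` to ``[0, 255]``. A constant
    frame is degenerate: a warning is raised and zeros are returned.
    """
    if not 0.0 < p < 100.0:
        raise ValueError("percentile must be in (0, 100)")
    frame = np.asarray(frame, dtype=float)
    lo = frame.min()
    hi = np.percentile(frame, p)
    if hi <= lo:
        warnings.warn(
            "degenerate frame: percentile equals minimum; returning zeros",
            DegenerateFrameWarning,
            stacklevel=2,
        )
        return np.zeros_like(frame)
    return np.clip((frame - lo) / (hi - lo), 0.0, 1.0) * 255.0


def ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Normalized correlation coefficient between two frames.

    ``sum((A-mean A)(B-mean B)) / sqrt(sum((A-mean A)^2) sum((B-mean B)^2))``
    over all pixels (optionally restricted to a boolean mask). Returns NaN
    with a :class:`DegenerateFrameWarning` when either frame has zero
    variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape must match the frames")
        a = a[mask]
        b = b[mask]
    da = a - a.mean()
    db = b - b.mean()
    va = np.sum(da * da)
    vb = np.sum(db * db)
    if va == 0.0 or vb == 0.0:
        warnings.warn(
            "zero-variance frame: NCC undefined, returning NaN",
            DegenerateFrameWarning,
            stacklevel=2,
        )
        return float("nan")
    return float(np.clip(np.sum(da * db) / np.sqrt(va * vb), -1.0, 1.0))


def preprocess_stack(
    stack: FrameStack,
    percentile: float = 97.0,
    per_sequence: bool = False,
) -> FrameStack:
    """Apply the fixed preprocessing chain to a stack.

    Medial-slice selection (for z-stacks), 3x3 median filtering, then
    percentile normalization. Normalization is per frame by default;
    ``per_sequence=True`` instead derives one affine map from the pooled
    histogram of the whole sequence.
    """
    frames = stack.frames.astype(float)
    if frames.ndim == 4:
        frames = frames[:, stack.medial_index]
    frames = np.stack([median_filter3(f) for f in frames])
    if per_sequence:
        lo = frames.min()
        hi = np.percentile(frames, percentile)
        if hi <= lo:
            warnings.warn(
                "degenerate sequence histogram; returning zeros",
                DegenerateFrameWarning,
                stacklevel=2,
            )
            frames = np.zeros_like(frames)
        else:
            frames = np.clip((frames - lo) / (hi - lo), 0.0, 1.0) * 255.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateFrameWarning)
            frames = np.stack([normalize_percentile(f, percentile) for f in frames])
    return FrameStack(frames, stack.frame_interval_s, 1)


def ncc_series(
    stack: FrameStack,
    cell_id: str = "cell",
    condition: str = "",
    mask: np.ndarray | None = None,
    preprocess: bool = False,
    percentile: float = 97.0,
) -> NCCSeries:
    """NCC of every frame against frame 0.

    The stack is expected to be preprocessed already (``preprocess=True``
    applies :func:`preprocess_stack` first). Degenerate frames yield NaN
    entries rather than silent numbers.
    """
    if preprocess:
        stack = preprocess_stack(stack, percentile=percentile)
    frames = stack.frames.astype(float)
    if frames.ndim == 4:
        frames = frames[:, stack.medial_index]
    ref = frames[0]
    values = np.empty(len(frames))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateFrameWarning)
        for t, frame in enumerate(frames):
            values[t] = ncc(ref, frame, mask=mask)
    return NCCSeries(cell_id, condition, stack.times_s, values)


def series_to_csv(series_list: list[NCCSeries], path) -> pd.DataFrame:
    """Write a list of series to a tidy CSV (cell_id, condition, time_s, ncc)."""
    df = pd.concat([s.to_frame() for s in series_list], ignore_index=True)
    df.to_csv(path, index=False)
    return df


def series_from_csv(path) -> list[NCCSeries]:
    """Read series back from the tidy CSV written by :func:`series_to_csv`."""
    df = pd.read_csv(path)
    out = []
    for (cell, cond), grp in df.groupby(["cell_id", "condition"], sort=False):
        grp = grp.sort_values("time_s")
        out.append(
            NCCSeries(str(cell), str(cond), grp["time_s"].values, grp["ncc"].values)
        )
    return out
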