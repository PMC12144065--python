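"""Pollen width by ellipse fit and hydration-rate time courses.

Pollen width is the minor-axis length of the ellipse with the same
normalized second central moments as the segmented pollen mask (the
moments-based fit used by Fiji's "fit ellipse"). The hydration rate at
time t is the percentage change of width relative to the width at t = 0:
``(L_t - L_0) / L_0 * 100``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "PollenTrack",
    "HydrationResult",
    "fit_ellipse_minor_axis",
    "segment_pollen",
    "hydration_rate",
    "hydration_timecourse",
    "tracks_from_csv",
    "tracks_to_csv",
]

DEFAULT_TIME_POINTS = (5.0, 10.0, 15.0)


@dataclass
class PollenTrack:
    """Per-pollen width measurements over time (t = 0 is L_0)."""

    pollen_id: str
    condition: str
    times_min: np.ndarray
    widths_um: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.widths_um = np.asarray(self.widths_um, dtype=float)
        if self.times_min.shape != self.widths_um.shape or self.times_min.ndim != 1:
            raise ValueError("times and widths must be 1-D vectors of equal length")
        if self.times_min[0] != 0.0:
            raise ValueError("a track must start at t = 0 (L_0)")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.widths_um <= 0):
            raise ValueError("widths must be positive")

    @property
    def L0(self) -> float:
        return float(self.widths_um[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pollen_id": self.pollen_id,
                "condition": self.condition,
                "time_min": self.times_min,
                "width_um": self.widths_um,
            }
        )


@dataclass
class HydrationResult:
    """Hydration rates (percent) of one pollen grain at requested times."""

    pollen_id: str
    condition: str
    times_min: np.ndarray
    rates_percent: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pollen_id": self.pollen_id,
                "condition": self.condition,
                "time_min": self.times_min,
                "hydration_rate_percent": self.rates_percent,
            }
        )


def fit_ellipse_minor_axis(mask: np.ndarray, pixel_size_um: float = 1.0) -> float:
    """Minor-axis length (µm) of the moments-equivalent ellipse of a mask.

    The mask must contain exactly one connected component; segment first if
    it does not.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    labels, n = label(mask, return_num=True)
    if n != 1:
        raise ValueError(f"mask has {n} connected components; segment first")
    props = regionprops(labels)[0]
    return float(props.axis_minor_length) * float(pixel_size_um)


def segment_pollen(frame: np.ndarray) -> np.ndarray:
    """Otsu threshold + largest connected component of a grayscale frame."""
    frame = np.asarray(frame, dtype=float)
    if frame.max() == frame.min():
        raise ValueError("blank frame: nothing to segment")
    bright = frame > threshold_otsu(frame)
    labels, n = label(bright, return_num=True)
    if n == 0:
        raise ValueError("no foreground component found")
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(sizes)) + 1)


def hydration_rate(L0: float, Lt: float) -> float:
    """Percentage change of pollen width relative to the initial width."""
    if L0 <= 0:
        raise ValueError("L0 must be positive")
    return (Lt - L0) / L0 * 100.0


def hydration_timecourse(
    track: PollenTrack,
    time_points=DEFAULT_TIME_POINTS,
    tolerance_min: float = 0.5,
) -> HydrationResult:
    """Hydration rate at the requested times, matched to the nearest sample.

    A requested time must lie within ``tolerance_min`` of a recorded sample
    (half the acquisition interval by default).
    """
    time_points = np.asarray(time_points, dtype=float)
    rates = np.empty(time_points.shape)
    for i, tp in enumerate(time_points):
        j = int(np.argmin(np.abs(track.times_min - tp)))
        if abs(track.times_min[j] - tp) > tolerance_min:
            raise ValueError(
                f"requested time {tp} min has no sample within {tolerance_min} min"
            )
        rates[i] = hydration_rate(track.L0, track.widths_um[j])
    return HydrationResult(track.pollen_id, track.condition, time_points, rates)


def tracks_to_csv(tracks: list[PollenTrack], path) -> pd.DataFrame:
    df = pd.concat([t.to_frame() for t in tracks], ignore_index=True)
    df.to_csv(path, index=False)
    return df


def tracks_from_csv(path) -> list[PollenTrack]:
    df = pd.read_csv(path)
    out = []
    for (pid, cond), grp in df.groupby(["pollen_id", "condition"], sort=False):
        grp = grp.sort_values("time_min")
        out.append(
            PollenTrack(str(pid), str(cond), grp["time_min"].values, grp["width_um"].values)
        )
    return out
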