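"""Automated counting of vacuole constriction events.

A constriction is scored when a new bright border appears completely across
the cell: per frame, bright pixels inside the cell mask are scanned row by
row; a row whose bright coverage reaches ``span_frac`` of the local cell
width is part of a candidate border, and a candidate that was absent at
that axial position over the preceding persistence window is a new event.
This automates a manual counting rule, so every parameter is an explicit,
validated default; pre-tabulated manual counts can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from vacmorph.morphodynamics import FrameStack
from vacmorph.synthetic import EventLog

__all__ = [
    "DetectorParams",
    "ConstrictionResult",
    "detect_constrictions",
    "compare_counts",
    "counts_from_csv",
]


@dataclass(frozen=True)
class DetectorParams:
    """Tunable thresholds of the border detector.

    span_frac:
        Fraction of the local cell width a bright run must cover to count
        as a border ("completely across" the cell, which tapers at the tip).
    persistence_frames:
        A border is new only if absent for this many preceding frames at
        that position; borders reappearing later are scored again (flagged
        in the event log output as separate events).
    merge_dist_px:
        Axial distance within which candidate rows belong to one border.
    """

    span_frac: float = 0.9
    persistence_frames: int = 2
    merge_dist_px: int = 5
    min_local_width_px: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.span_frac <= 1:
            raise ValueError("span_frac must be in (0, 1]")
        if self.persistence_frames < 1 or self.merge_dist_px < 0:
            raise ValueError("invalid temporal/spatial parameters")


@dataclass
class ConstrictionResult:
    """Constriction count for one cell within a scoring window."""

    cell_id: str
    condition: str = ""
    window_s: float = 600.0
    detections: EventLog = field(default_factory=EventLog)

    @property
    def count(self) -> int:
        return self.detections.count("constriction", window_s=self.window_s)


def _border_rows(
    frame: np.ndarray, mask: np.ndarray, params: DetectorParams
) -> np.ndarray:
    """Rows whose bright coverage spans >= span_frac of the local cell width."""
    inside = frame[mask]
    if inside.max() <= inside.min():
        return np.zeros(frame.shape[0], dtype=bool)
    thr = threshold_otsu(inside)
    bright = (frame > thr) & mask
    width = mask.sum(axis=1)
    cover = bright.sum(axis=1)
    rows = np.zeros(frame.shape[0], dtype=bool)
    ok = width >= params.min_local_width_px
    rows[ok] = cover[ok] >= params.span_frac * width[ok]
    return rows


def _cluster_rows(rows: np.ndarray, merge_dist: int) -> list[float]:
    """Centers of runs of candidate rows, merging runs closer than merge_dist."""
    idx = np.flatnonzero(rows)
    if idx.size == 0:
        return []
    groups: list[list[int]] = [[int(idx[0])]]
    for y in idx[1:]:
        if y - groups[-1][-1] <= merge_dist:
            groups[-1].append(int(y))
        else:
            groups.append([int(y)])
    return [float(np.mean(g)) for g in groups]


def detect_constrictions(
    stack: FrameStack,
    cell_mask: np.ndarray,
    params: DetectorParams | None = None,
    cell_id: str = "cell",
    condition: str = "",
    window_s: float = 600.0,
) -> ConstrictionResult:
    """Detect new full-width borders in a preprocessed movie.

    Deterministic given inputs and parameters; the returned event log holds
    one constriction per appearance (time of the first frame the border is
    visible, axial position as a fraction of the masked cell extent).
    """
    params = params or DetectorParams()
    cell_mask = np.asarray(cell_mask).astype(bool)
    frames = stack.frames
    if frames.ndim != 3:
        raise ValueError("stack must be 2-D frames (select the medial slice first)")
    if cell_mask.shape != frames.shape[1:]:
        raise ValueError("mask shape does not match the frames")
    if not cell_mask.any():
        raise ValueError("empty cell mask")

    mask_rows = np.flatnonzero(cell_mask.any(axis=1))
    y0, y1 = int(mask_rows[0]), int(mask_rows[-1])
    extent = max(y1 - y0, 1)

    history: list[list[float]] = []
    events: list[tuple[float, str, float]] = []
    for t in range(stack.n_frames):
        centers = _cluster_rows(
            _border_rows(frames[t], cell_mask, params), params.merge_dist_px
        )
        recent = [
            c
            for past in history[-params.persistence_frames :]
            for c in past
        ]
        for c in centers:
            is_new = t > 0 and all(abs(c - r) > params.merge_dist_px for r in recent)
            if is_new:
                events.append(
                    (t * stack.frame_interval_s, "constriction", (c - y0) / extent)
                )
        history.append(centers)

    return ConstrictionResult(cell_id, condition, window_s, EventLog(events))


def compare_counts(results_by_condition: dict[str, list[int]]) -> pd.DataFrame:
    """Per-condition summary table: mean, SEM (sd/sqrt(n)), and n."""
    rows = []
    for condition, counts in results_by_condition.items():
        counts = np.asarray(list(counts), dtype=float)
        if counts.size == 0:
            raise ValueError(f"condition {condition!r} has no results")
        n = counts.size
        sem = float(counts.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {"condition": condition, "mean": float(counts.mean()), "sem": sem, "n": n}
        )
    return pd.DataFrame(rows)


def counts_from_csv(path) -> dict[str, list[int]]:
    """Read manual counts (columns: condition, count), bypassing detection."""
    df = pd.read_csv(path)
    if not {"condition", "count"} <= set(df.columns):
        raise ValueError("manual count CSV needs 'condition' and 'count' columns")
    return {
        str(cond): [int(c) for c in grp["count"]]
        for cond, grp in df.groupby("condition", sort=False)
    }
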