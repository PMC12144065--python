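"""Synthetic inputs for the whole pipeline.

Three generators, each with a known ground truth:

* tonoplast time-lapse movies of a single elongated (papilla-like) cell with
  a bright membrane outline of a central vacuole, satellite vacuoles, and
  scenario-controlled constriction/fusion events (`simulate_vacuole_sequence`);
* NCC series drawn directly from the Bayesian state-space observation model
  (`simulate_ncc_series`);
* pollen hydration image sequences / width tables following a saturating
  exponential width trajectory (`simulate_pollen_assay`).

Scenario presets encode the qualitative orderings of the experimental
conditions (untreated/pollinated, mock, E-64d, PDMP, wortmannin dose series,
rop2 mutant).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import binary_erosion

from vacmorph.hydration import PollenTrack
from vacmorph.morphodynamics import FrameStack

__all__ = [
    "Scenario",
    "EventLog",
    "SSMTruth",
    "CellGeometry",
    "simulate_vacuole_sequence",
    "simulate_ncc_series",
    "simulate_pollen_assay",
    "scenario_presets",
    "hydration_preset",
    "wortmannin_constriction_rate",
    "PRESET_NAMES",
    "write_tiff",
    "read_tiff",
]

# rendering intensities (8-bit scale)
_BACKGROUND = 8.0
_CYTOPLASM = 30.0
_MEMBRANE = 200.0
_SATELLITE = 180.0


@dataclass(frozen=True)
class Scenario:
    """Parameter bundle for one synthetic movie condition.

    Rates are expected event counts per 10 minutes of imaging.
    """

    name: str
    constriction_rate: float
    fusion_rate: float
    satellite_vacuole_count: int
    invagination: bool = False
    noise_sd: float = 0.0
    shot_noise_scale: float = 0.0
    frame_count: int = 60
    frame_interval_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_count < 2:
            raise ValueError("frame_count must be >= 2")
        if self.constriction_rate < 0 or self.fusion_rate < 0:
            raise ValueError("event rates must be nonnegative")
        if self.satellite_vacuole_count < 0:
            raise ValueError("satellite_vacuole_count must be >= 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.noise_sd < 0 or self.shot_noise_scale < 0:
            raise ValueError("noise magnitudes must be nonnegative")

    @property
    def duration_s(self) -> float:
        return (self.frame_count - 1) * self.frame_interval_s

    def replace(self, **kwargs) -> "Scenario":
        return dataclasses.replace(self, **kwargs)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Scenario":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class EventLog:
    """Timestamped constriction/fusion events with axial positions.

    ``position`` is the axial fraction along the cell (0 = tip, 1 = base).
    """

    events: list[tuple[float, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e[0])
        for t, kind, pos in self.events:
            if kind not in ("constriction", "fusion"):
                raise ValueError(f"unknown event kind {kind!r}")
            if t < 0:
                raise ValueError("event times must be nonnegative")

    def __len__(self) -> int:
        return len(self.events)

    def count(self, kind: str | None = None, window_s: float | None = None) -> int:
        n = 0
        for t, k, _ in self.events:
            if kind is not None and k != kind:
                continue
            if window_s is not None and t > window_s:
                continue
            n += 1
        return n

    @property
    def times_s(self) -> np.ndarray:
        return np.array([t for t, _, _ in self.events])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["time_s", "kind", "position"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventLog":
        df = pd.read_csv(path)
        return cls([(float(r.time_s), str(r.kind), float(r.position)) for r in df.itertuples()])


@dataclass(frozen=True)
class SSMTruth:
    """Ground-truth parameters for the generative state-space model."""

    mu: np.ndarray
    delta: np.ndarray
    kappa: float
    n_cells_control: int = 5
    n_cells_experimental: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "delta", np.asarray(self.delta, dtype=float))
        if self.mu.shape != self.delta.shape or self.mu.ndim != 1:
            raise ValueError("mu and delta must be 1-D vectors of equal length")
        if np.any((self.mu <= 0) | (self.mu >= 1)):
            raise ValueError("all mu[t] must lie in (0, 1)")
        nu = self.mu + self.delta
        if np.any((nu <= 0) | (nu >= 1)):
            raise ValueError("all mu[t] + delta[t] must lie in (0, 1)")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.n_cells_control < 1 or self.n_cells_experimental < 1:
            raise ValueError("need at least one cell per group")

    @property
    def T(self) -> int:
        return len(self.mu)


# ---------------------------------------------------------------------------
# cell geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellGeometry:
    """2-D capsule (rectangle + hemispherical tip) standing in for the cell.

    The tip is at the top of the image; pixel dimensions are free parameters
    chosen so membrane lines are several pixels wide at 8-bit depth.
    """

    height: int = 140
    width: int = 44
    half_width: int = 15
    tip_y: int = 6
    base_y: int = 132
    vacuole_margin: int = 5

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.base_y - self.tip_y < 4 * self.vacuole_margin:
            raise ValueError("cell too short for the vacuole margin")

    @property
    def cx(self) -> float:
        return (self.width - 1) / 2.0

    @property
    def axial_length(self) -> float:
        return float(self.base_y - self.tip_y)

    def _capsule(self, half_width: int, top: int, bottom: int) -> np.ndarray:
        yy, xx = np.mgrid[0 : self.height, 0 : self.width]
        dx = np.abs(xx - self.cx)
        hw = np.full(self.height, -1.0)
        ys = np.arange(self.height)
        cap = (ys >= top) & (ys < top + half_width)
        straight = (ys >= top + half_width) & (ys <= bottom)
        hw[straight] = half_width
        dy = half_width - (ys[cap] - top)
        hw[cap] = np.sqrt(np.maximum(half_width**2 - dy**2, 0.0))
        return dx <= hw[yy]

    def cell_mask(self) -> np.ndarray:
        return self._capsule(self.half_width, self.tip_y, self.base_y)

    def vacuole_mask(self) -> np.ndarray:
        m = self.vacuole_margin
        return self._capsule(
            self.half_width - m, self.tip_y + m, self.base_y - m
        )

    def vacuole_contour(self, invagination: bool = False) -> np.ndarray:
        """Bright closed membrane outline (~2 px thick) of the central vacuole."""
        inner = self.vacuole_mask()
        if invagination:
            # inward pinches: carve static wedges off the vacuole sides
            yy, xx = np.mgrid[0 : self.height, 0 : self.width]
            wave = 2.5 * (1.0 + np.sin(yy / 7.0)) / 2.0
            inner = inner & (
                np.abs(xx - self.cx) <= (self.half_width - self.vacuole_margin) - wave
            )
        eroded = binary_erosion(inner, iterations=2, border_value=0)
        return inner & ~eroded

    def local_width(self, y: int) -> int:
        return int(self.cell_mask()[y].sum())

    def axial_fraction(self, y: float) -> float:
        return float((y - self.tip_y) / self.axial_length)

    def y_from_fraction(self, frac: float) -> int:
        return int(round(self.tip_y + frac * self.axial_length))


# ---------------------------------------------------------------------------
# movie generator
# ---------------------------------------------------------------------------


def _sample_constrictions(
    scenario: Scenario, geometry: CellGeometry, rng: np.random.Generator
) -> list[tuple[int, int, int]]:
    """Sample (start_frame, duration_frames, row) for constriction bands.

    Candidates too close in time AND axial position to an accepted event are
    dropped so every logged event renders as a distinct new border.
    """
    duration_min = scenario.duration_s / 60.0
    n = rng.poisson(scenario.constriction_rate * duration_min / 10.0)
    # rows restricted to the straight section so the border spans full width
    y_lo = geometry.tip_y + geometry.half_width + geometry.vacuole_margin + 3
    y_hi = geometry.base_y - geometry.vacuole_margin - 3
    accepted: list[tuple[int, int, int]] = []
    for _ in range(n):
        dur = int(rng.integers(3, 6))
        start = int(rng.integers(1, max(2, scenario.frame_count - dur)))
        row = int(rng.integers(y_lo, y_hi + 1))
        clash = any(
            abs(row - r0) < 12 and start <= s0 + d0 + 2 and s0 <= start + dur + 2
            for s0, d0, r0 in accepted
        )
        if not clash:
            accepted.append((start, dur, row))
    return sorted(accepted)


def simulate_vacuole_sequence(
    scenario: Scenario, geometry: CellGeometry | None = None
) -> tuple[FrameStack, EventLog]:
    """Render a tonoplast movie plus its ground-truth event log.

    Each constriction event appears as a bright border spanning the full
    transverse width of the cell for >= 2 consecutive frames; each fusion
    event absorbs one satellite vacuole. Noise (Poisson shot + Gaussian
    read) is added after geometry rendering. Fully deterministic under the
    scenario seed.
    """
    geometry = geometry or CellGeometry()
    rng = np.random.default_rng(scenario.seed)

    cell = geometry.cell_mask()
    contour = geometry.vacuole_contour(scenario.invagination)

    # satellite vacuoles in the corridor between vacuole and cell wall
    sat_offset = geometry.half_width - geometry.vacuole_margin / 2.0 - 0.5
    y_lo = geometry.tip_y + geometry.half_width + 4
    y_hi = geometry.base_y - geometry.vacuole_margin - 4
    satellites = []
    for _ in range(scenario.satellite_vacuole_count):
        side = 1 if rng.random() < 0.5 else -1
        sy = int(rng.integers(y_lo, y_hi + 1))
        satellites.append((sy, geometry.cx + side * sat_offset))

    constrictions = _sample_constrictions(scenario, geometry, rng)

    # fusion events: satellites absorbed one at a time
    duration_min = scenario.duration_s / 60.0
    n_fusion = min(
        rng.poisson(scenario.fusion_rate * duration_min / 10.0), len(satellites)
    )
    fusion_frames = sorted(
        int(f) for f in rng.choice(np.arange(1, scenario.frame_count), size=n_fusion, replace=False)
    ) if n_fusion > 0 else []
    fusion_order = rng.permutation(len(satellites))[:n_fusion]

    yy, xx = np.mgrid[0 : geometry.height, 0 : geometry.width]
    sat_disks = [
        (np.hypot(yy - sy, xx - sx) <= 2.2) for sy, sx in satellites
    ]

    events: list[tuple[float, str, float]] = []
    for start, dur, row in constrictions:
        events.append(
            (start * scenario.frame_interval_s, "constriction", geometry.axial_fraction(row))
        )
    for f, idx in zip(fusion_frames, fusion_order):
        sy, _ = satellites[idx]
        events.append((f * scenario.frame_interval_s, "fusion", geometry.axial_fraction(sy)))

    frames = np.empty((scenario.frame_count, geometry.height, geometry.width))
    for t in range(scenario.frame_count):
        frame = np.full((geometry.height, geometry.width), _BACKGROUND)
        frame[cell] = _CYTOPLASM
        frame[contour] = _MEMBRANE
        for i, disk in enumerate(sat_disks):
            absorbed = any(
                f <= t for f, j in zip(fusion_frames, fusion_order) if j == i
            )
            if not absorbed:
                frame[disk & cell] = _SATELLITE
        for start, dur, row in constrictions:
            if start <= t < start + dur:
                band = (np.abs(yy - row) <= 1) & cell
                frame[band] = _MEMBRANE
            elif t >= start + dur:
                # resolved constrictions leave a lasting partial border
                # (60% of local width: morphology changed, but no longer a
                # full-width event for the detector)
                band = (np.abs(yy - row) <= 1) & cell
                band &= np.abs(xx - geometry.cx) <= 0.3 * cell[row].sum()
                frame[band] = _MEMBRANE
        if scenario.shot_noise_scale > 0:
            frame = rng.poisson(frame * scenario.shot_noise_scale) / scenario.shot_noise_scale
        if scenario.noise_sd > 0:
            frame = frame + rng.normal(0.0, scenario.noise_sd, frame.shape)
        frames[t] = np.clip(frame, 0.0, 255.0)

    stack = FrameStack(frames, scenario.frame_interval_s, 1)
    return stack, EventLog(events)


# ---------------------------------------------------------------------------
# generative NCC series
# ---------------------------------------------------------------------------


def simulate_ncc_series(truth: SSMTruth) -> tuple[np.ndarray, np.ndarray]:
    """Draw NCC observations from the Beta-proportion observation model.

    Returns arrays of shape ``(n_cells_control, T)`` and
    ``(n_cells_experimental, T)``; the control group is drawn from
    ``Beta(mu*kappa, (1-mu)*kappa)`` and the experimental group from the
    same law at mean ``mu + delta``. All values lie in the open interval
    (0, 1).
    """
    rng = np.random.default_rng(truth.seed)
    mu = truth.mu
    nu = truth.mu + truth.delta
    k = truth.kappa
    control = rng.beta(mu * k, (1.0 - mu) * k, size=(truth.n_cells_control, truth.T))
    experimental = rng.beta(nu * k, (1.0 - nu) * k, size=(truth.n_cells_experimental, truth.T))
    tiny = np.finfo(float).tiny
    return (
        np.clip(control, tiny, 1.0 - 1e-15),
        np.clip(experimental, tiny, 1.0 - 1e-15),
    )


# ---------------------------------------------------------------------------
# pollen hydration assay
# ---------------------------------------------------------------------------


def simulate_pollen_assay(
    L0: float,
    plateau_rate: float,
    tau: float,
    interval: float = 1.0,
    duration: float = 15.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    pollen_id: str = "pollen",
    condition: str = "",
    render: bool = False,
    pixel_size_um: float = 0.5,
    aspect: float = 1.25,
) -> PollenTrack | tuple[PollenTrack, np.ndarray]:
    """Synthetic pollen width trajectory (and optional ellipse-mask frames).

    Width follows ``L_t = L0 * (1 + (plateau_rate/100) * (1 - exp(-t/tau)))``
    plus optional Gaussian noise; frames (if requested) are filled ellipses
    whose minor axis is ``L_t``.
    """
    if L0 <= 0:
        raise ValueError("L0 must be positive")
    if duration < interval:
        raise ValueError("duration must be at least one interval")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + interval / 2.0, interval)
    widths = L0 * (1.0 + plateau_rate / 100.0 * (1.0 - np.exp(-times / tau)))
    if noise_sd > 0:
        widths = widths + rng.normal(0.0, noise_sd, widths.shape)
    widths = np.maximum(widths, 1e-6)
    track = PollenTrack(pollen_id, condition, times, widths)
    if not render:
        return track
    frames = _render_ellipse_frames(widths, pixel_size_um, aspect)
    return track, frames


def _render_ellipse_frames(
    widths_um: np.ndarray, pixel_size_um: float, aspect: float
) -> np.ndarray:
    max_minor_px = widths_um.max() / pixel_size_um
    size = int(np.ceil(max_minor_px * aspect)) + 12
    cy = cx = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    frames = np.zeros((len(widths_um), size, size), dtype=np.uint8)
    for i, w in enumerate(widths_um):
        b = w / pixel_size_um / 2.0  # semi-minor (horizontal)
        a = b * aspect  # semi-major (vertical)
        inside = ((xx - cx) / b) ** 2 + ((yy - cy) / a) ** 2 <= 1.0
        frames[i][inside] = 255
    return frames


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

_BASE_RATE = 6.0  # constrictions per 10 min in untreated, unpollinated cells
_BASE_FUSION = 3.0
_BASE_NOISE = 6.0

PRESET_NAMES = (
    "unpollinated",
    "pollinated",
    "mock",
    "e64d",
    "pdmp",
    "wortmannin",
    "rop2_unpollinated",
    "rop2_pollinated",
)


def wortmannin_constriction_rate(dose_um: float) -> float:
    """Dose-monotone constriction rate; equals the mock rate at dose 0."""
    if dose_um < 0:
        raise ValueError("dose must be nonnegative")
    return _BASE_RATE / (1.0 + dose_um / 10.0)


def scenario_presets(name: str, dose_um: float = 500.0, seed: int = 0) -> Scenario:
    """Deterministic parameter bundles for the experimental conditions.

    Rates are free parameters chosen to reproduce the qualitative ordering
    of the conditions (E-64d > mock ~ unpollinated > PDMP ~ high-dose
    wortmannin ~ pollinated), not measured values. ``"wortmannin_<dose>"``
    is accepted as shorthand for the dose series.
    """
    if name.startswith("wortmannin_"):
        dose_um = float(name.split("_", 1)[1])
        name = "wortmannin"
    common = dict(noise_sd=_BASE_NOISE, frame_count=60, frame_interval_s=10.0, seed=seed)
    if name == "unpollinated":
        return Scenario("unpollinated", _BASE_RATE, _BASE_FUSION, 4, **common)
    if name == "mock":
        # mock-treated cells behave the same as untreated unpollinated cells
        return Scenario("mock", _BASE_RATE, _BASE_FUSION, 4, **common)
    if name == "pollinated":
        return Scenario("pollinated", 0.8, 1.0, 1, **common)
    if name == "e64d":
        return Scenario("e64d", 2.0 * _BASE_RATE, 0.5, 6, **common)
    if name == "pdmp":
        return Scenario("pdmp", 0.8, 5.0, 3, **common)
    if name == "wortmannin":
        if dose_um == 0:
            return scenario_presets("mock", seed=seed)
        rate = wortmannin_constriction_rate(dose_um)
        return Scenario(
            f"wortmannin_{dose_um:g}",
            rate,
            _BASE_FUSION * (1.0 + dose_um / 250.0),
            max(0, round(4.0 / (1.0 + dose_um / 100.0))),
            invagination=dose_um >= 10.0,
            **common,
        )
    if name == "rop2_unpollinated":
        return Scenario("rop2_unpollinated", 3.0, _BASE_FUSION, 2, **common)
    if name == "rop2_pollinated":
        return Scenario("rop2_pollinated", 0.4, 1.0, 0, **common)
    raise ValueError(f"unknown scenario preset {name!r}")


_BASE_PLATEAU = 40.0  # percent width gain at the hydration plateau
_BASE_TAU = 3.0  # minutes


def hydration_preset(name: str, dose_um: float = 500.0) -> dict:
    """Keyword arguments for :func:`simulate_pollen_assay` per condition.

    Wortmannin suppresses the plateau monotonically with dose (equal to mock
    at dose 0); the rop2 mutant hydrates faster.
    """
    if name.startswith("wortmannin_"):
        dose_um = float(name.split("_", 1)[1])
        name = "wortmannin"
    base = dict(L0=20.0, plateau_rate=_BASE_PLATEAU, tau=_BASE_TAU)
    if name in ("mock", "unpollinated", "pollinated", "e64d", "pdmp"):
        return base
    if name == "wortmannin":
        if dose_um < 0:
            raise ValueError("dose must be nonnegative")
        return dict(
            L0=20.0,
            plateau_rate=_BASE_PLATEAU / (1.0 + dose_um / 66.0),
            tau=_BASE_TAU,
        )
    if name in ("rop2_unpollinated", "rop2_pollinated", "rop2"):
        return dict(L0=20.0, plateau_rate=48.0, tau=1.8)
    raise ValueError(f"unknown hydration preset {name!r}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_tiff(stack: FrameStack, path, dtype=np.uint8) -> None:
    """Write a stack as a multi-page grayscale TIFF (8- or 16-bit)."""
    info = np.iinfo(dtype)
    data = np.clip(np.round(stack.frames), info.min, info.max).astype(dtype)
    tifffile.imwrite(path, data, photometric="minisblack")


def read_tiff(path, frame_interval_s: float = 10.0, z_slices_per_timepoint: int = 1) -> FrameStack:
    """Read a multi-page TIFF back into a :class:`FrameStack`."""
    data = tifffile.imread(path)
    if z_slices_per_timepoint > 1 and data.ndim == 3:
        t = data.shape[0] // z_slices_per_timepoint
        data = data[: t * z_slices_per_timepoint].reshape(
            t, z_slices_per_timepoint, *data.shape[1:]
        )
    return FrameStack(np.asarray(data, dtype=float), frame_interval_s, z_slices_per_timepoint)
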