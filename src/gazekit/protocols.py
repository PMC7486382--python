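"""Oculomotor task protocols and their per-trial metrics.

Three tasks are modelled:

* **Prosaccade** — central fixation cross for 800 ms, then a pulsating
  circular target (60 to 168 px, three pulses over 1000 ms) at a location
  sampled uniformly over the screen; the metric is saccade latency.
* **Smooth pursuit** — a dot moving clockwise around a circle centred on
  the screen at ~7 degrees eccentricity, starting and ending at the
  right-most point (or a concentric box, or a top-left to bottom-right
  zig-zag); the metric is mean gaze-to-target tracking error in cm.
* **Visual search** — a display of items of which exactly one (the
  target) differs from the distractors in orientation (by delta-theta
  degrees) or colour intensity; the metrics are the number of fixations
  and total fixation time until the target is first fixated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .events import OculomotorEvent
from .geometry import GazeSample, ScreenGeometry, degrees_to_cm

__all__ = [
    "ProsaccadeTrial",
    "PursuitPath",
    "SearchItem",
    "SearchDisplay",
    "DotCalibrationProtocol",
    "generate_prosaccade_trial",
    "generate_pursuit_path",
    "pursuit_tracking_error",
    "generate_search_display",
    "fixations_to_target",
]


@dataclass(frozen=True)
class ProsaccadeTrial:
    """One prosaccade trial: central fixation, then a peripheral target."""

    target: Tuple[float, float]
    fixation_ms: float = 800.0
    target_duration_ms: float = 1000.0
    marker_pulse_px: Tuple[float, float] = (60.0, 168.0)
    n_pulses: int = 3

    def __post_init__(self) -> None:
        if self.fixation_ms <= 0 or self.target_duration_ms <= 0:
            raise ValueError("durations must be positive")

    @property
    def stimulus_onset_s(self) -> float:
        return self.fixation_ms / 1000.0

    @property
    def total_duration_s(self) -> float:
        return (self.fixation_ms + self.target_duration_ms) / 1000.0


def generate_prosaccade_trial(g: ScreenGeometry, rng: np.random.Generator) -> ProsaccadeTrial:
    """Target uniformly sampled across the full screen area."""
    x = float(rng.uniform(0, g.width_px))
    y = float(rng.uniform(0, g.height_px))
    return ProsaccadeTrial(target=(x, y))


@dataclass(frozen=True)
class PursuitPath:
    """A timestamped smooth-pursuit target path."""

    shape: str  # circle | box | zigzag
    t: np.ndarray
    xy: np.ndarray
    period_s: float
    eccentricity_deg: Optional[float] = None

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def at(self, times: np.ndarray) -> np.ndarray:
        """Linearly interpolated target position at arbitrary times."""
        times = np.asarray(times, dtype=float)
        x = np.interp(times, self.t, self.xy[:, 0])
        y = np.interp(times, self.t, self.xy[:, 1])
        return np.stack([x, y], axis=1)


def generate_pursuit_path(shape: str, g: ScreenGeometry, period_s: float = 8.0,
                          rate_hz: float = 30.0, eccentricity_deg: float = 7.0,
                          n_cycles: int = 1) -> PursuitPath:
    """Build a pursuit target path.

    The circle is centred on the screen with radius
    ``viewing_distance * tan(eccentricity)`` converted to px, traversed
    clockwise (under the y-down screen convention) starting and ending at
    its right-most point.  The box is the square concentric with the
    circle's bounding box, traversed with the same period.  The zig-zag
    sweeps from top-left to bottom-right.
    """
    n = int(round(period_s * rate_hz * n_cycles)) + 1
    t = np.arange(n) / rate_hz
    cx, cy = g.center_px
    if shape in ("circle", "box"):
        r_cm = degrees_to_cm(eccentricity_deg, g.viewing_distance_cm)
        r_px = r_cm * g.px_per_cm
        if r_px > min(g.width_px, g.height_px) / 2:
            raise ValueError("pursuit radius exceeds screen half-extent")
        if shape == "circle":
            theta = 2 * math.pi * (t / period_s)
            xy = np.stack([cx + r_px * np.cos(theta), cy + r_px * np.sin(theta)], axis=1)
        else:
            # clockwise square of half-side r, starting mid right edge
            s = (t / period_s) % 1.0
            xy = np.empty((n, 2))
            for i, si in enumerate(s * 8):
                if si < 1:      # right edge, downwards from middle
                    p = (r_px, si * r_px)
                elif si < 3:    # bottom edge, rightward->leftward
                    p = (r_px - (si - 1) * r_px, r_px)
                elif si < 5:    # left edge, upwards
                    p = (-r_px, r_px - (si - 3) * r_px)
                elif si < 7:    # top edge, leftward->rightward
                    p = (-r_px + (si - 5) * r_px, -r_px)
                else:           # right edge, back to middle
                    p = (r_px, -r_px + (si - 7) * r_px)
                xy[i] = (cx + p[0], cy + p[1])
        xy[-1] = xy[0]  # exact closure
        return PursuitPath(shape, t, xy, period_s, eccentricity_deg)
    if shape == "zigzag":
        margin = 0.05
        n_rows = 6
        x0, x1 = margin * g.width_px, (1 - margin) * g.width_px
        y0, y1 = margin * g.height_px, (1 - margin) * g.height_px
        frac = t / t[-1]
        y = y0 + frac * (y1 - y0)
        saw = frac * n_rows % 2.0
        xfrac = np.where(saw <= 1.0, saw, 2.0 - saw)
        x = x0 + xfrac * (x1 - x0)
        return PursuitPath(shape, t, np.stack([x, y], axis=1), period_s)
    raise ValueError(f"unknown pursuit shape: {shape}")


def pursuit_tracking_error(trace: Sequence[GazeSample], path: PursuitPath,
                           g: ScreenGeometry) -> float:
    """Mean Euclidean gaze-to-target distance in cm over the trial.

    The path is interpolated at each gaze timestamp; gaze samples outside
    the path's time span are ignored, and fully disjoint ranges are an
    error.
    """
    t = np.array([s.t for s in trace])
    xy = np.array([[s.x, s.y] for s in trace])
    keep = (t >= path.t[0]) & (t <= path.t[-1])
    if not np.any(keep):
        raise ValueError("trace and path time ranges are disjoint")
    target = path.at(t[keep])
    d_px = np.linalg.norm(xy[keep] - target, axis=1)
    return float(d_px.mean()) / g.px_per_cm


@dataclass(frozen=True)
class SearchItem:
    position: Tuple[float, float]
    is_target: bool
    feature: float  # orientation in degrees, or colour intensity in [0,1]


@dataclass(frozen=True)
class SearchDisplay:
    """A single-target search display."""

    set_size: int
    mode: str  # orientation | color_intensity
    contrast: float  # delta-theta degrees, or intensity difference
    items: Tuple[SearchItem, ...]
    item_radius_px: float = 60.0

    def __post_init__(self) -> None:
        if sum(i.is_target for i in self.items) != 1:
            raise ValueError("display must contain exactly one target")
        if len(self.items) != self.set_size:
            raise ValueError("set_size must equal the number of items")

    @property
    def target(self) -> SearchItem:
        return next(i for i in self.items if i.is_target)

    @property
    def distractors(self) -> List[SearchItem]:
        return [i for i in self.items if not i.is_target]


@dataclass(frozen=True)
class DotCalibrationProtocol:
    """Pulsating green-dot calibration marker parameters."""

    pulse_dp: Tuple[float, float] = (18.0, 50.0)
    pulse_period_ms: float = 300.0
    zigzag_duration_s: float = 60.0

    def __post_init__(self) -> None:
        lo, hi = self.pulse_dp
        if not (0 < lo < hi):
            raise ValueError("marker pulse sizes must satisfy 0 < min < max")


def generate_search_display(set_size: int, mode: str, contrast: float, seed: int,
                            g: ScreenGeometry, item_radius_px: float = 60.0,
                            min_spacing_factor: float = 3.0) -> SearchDisplay:
    """Reproducible random search display with one diverging target.

    Items are placed by rejection sampling with a minimum centre spacing
    of ``min_spacing_factor * item_radius_px``.  In orientation mode all
    distractors share one orientation and the target differs by
    ``contrast`` degrees; in colour-intensity mode the target differs by
    ``contrast`` intensity units.
    """
    if set_size < 2:
        raise ValueError("set_size must be at least 2")
    if mode not in ("orientation", "color_intensity"):
        raise ValueError(f"unknown search mode: {mode}")
    if contrast <= 0:
        raise ValueError("target indistinguishable: contrast must be positive")
    rng = np.random.default_rng(seed)
    margin = 2 * item_radius_px
    min_d = min_spacing_factor * item_radius_px
    positions: List[np.ndarray] = []
    attempts = 0
    while len(positions) < set_size:
        attempts += 1
        if attempts > 5000:
            raise ValueError("set_size too large for non-overlapping placement")
        p = np.array([rng.uniform(margin, g.width_px - margin),
                      rng.uniform(margin, g.height_px - margin)])
        if all(np.linalg.norm(p - q) >= min_d for q in positions):
            positions.append(p)
    target_idx = int(rng.integers(set_size))
    if mode == "orientation":
        base = float(rng.uniform(0, 180))
        feat = lambda is_t: (base + contrast) % 180 if is_t else base
    else:
        base = float(rng.uniform(0.2, 0.8 - contrast))
        feat = lambda is_t: base + contrast if is_t else base
    items = tuple(
        SearchItem(position=(float(p[0]), float(p[1])), is_target=(i == target_idx),
                   feature=feat(i == target_idx))
        for i, p in enumerate(positions)
    )
    return SearchDisplay(set_size, mode, contrast, items, item_radius_px)


def fixations_to_target(events: Sequence[OculomotorEvent], display: SearchDisplay,
                        radius_px: Optional[float] = None
                        ) -> Tuple[Optional[int], Optional[float]]:
    """Search performance: fixations and dwell time until the target is hit.

    Returns ``(count, total_duration_s)`` where ``count`` is the 1-based
    index of the first fixation whose centroid falls within ``radius_px``
    of the target (default 1.5 x item radius) and the duration sums all
    fixations up to and including it.  ``(None, None)`` when no fixation
    reaches the target.
    """
    if radius_px is None:
        radius_px = 1.5 * display.item_radius_px
    tgt = np.asarray(display.target.position)
    fixations = [e for e in events if e.kind == "fixation"]
    times = [e.onset for e in fixations]
    if times != sorted(times):
        raise ValueError("events must be time-ordered")
    total = 0.0
    for i, f in enumerate(fixations, start=1):
        total += f.duration
        if np.linalg.norm(np.asarray(f.centroid) - tgt) <= radius_px:
            return i, total
    return None, None
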