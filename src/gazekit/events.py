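"""Oculomotor event detection from raw gaze traces.

The pipeline is the classic I-VT (identification by velocity threshold)
recipe for low-rate phone gaze: smooth the raw trace with a bilateral
filter (scale 100 ms in time, 200 px in space), compute instantaneous
angular velocity by central differences, label samples moving at or above
22 deg/s as saccade and the rest as fixation, then merge fixation runs and
drop those shorter than 100 ms.  Velocities are converted to visual
degrees through :class:`~gazekit.geometry.ScreenGeometry`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .geometry import GazeSample, ScreenGeometry, Stage, cm_to_degrees, snap_to_screen

__all__ = [
    "EventConfig",
    "OculomotorEvent",
    "bilateral_smooth",
    "classify_ivt",
    "extract_events",
    "extract_fixations",
    "saccade_latency",
    "aggregate_per_stimulus",
    "trace_to_arrays",
    "arrays_to_trace",
]


@dataclass(frozen=True)
class EventConfig:
    """Detection parameters; defaults are the values used throughout."""

    velocity_threshold_deg_s: float = 22.0
    min_fixation_ms: float = 100.0
    bilateral_time_ms: float = 100.0
    bilateral_space_px: float = 200.0
    onset_discard_ms: float = 800.0
    max_gap_ms: float = 100.0  # samples further apart than this break runs

    def __post_init__(self) -> None:
        for name in ("velocity_threshold_deg_s", "min_fixation_ms",
                     "bilateral_time_ms", "bilateral_space_px",
                     "onset_discard_ms", "max_gap_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class OculomotorEvent:
    """A fixation (with centroid) or saccade (with amplitude)."""

    kind: str  # "fixation" | "saccade"
    onset: float
    offset: float
    centroid: Optional[Tuple[float, float]] = None
    amplitude_deg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("fixation", "saccade"):
            raise ValueError("kind must be 'fixation' or 'saccade'")
        if not self.offset > self.onset:
            raise ValueError("event offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def trace_to_arrays(trace: Sequence[GazeSample]) -> Tuple[np.ndarray, np.ndarray]:
    t = np.array([s.t for s in trace], dtype=float)
    xy = np.array([[s.x, s.y] for s in trace], dtype=float)
    return t, xy


def arrays_to_trace(t: np.ndarray, xy: np.ndarray, stage: Stage = Stage.RAW) -> List[GazeSample]:
    return [GazeSample(float(ti), float(p[0]), float(p[1]), stage) for ti, p in zip(t, xy)]


def _check_sorted(t: np.ndarray) -> None:
    if np.any(np.diff(t) < 0):
        raise ValueError("trace must be time-sorted")


def bilateral_smooth(trace: Sequence[GazeSample], cfg: EventConfig = EventConfig()) -> List[GazeSample]:
    """Edge-preserving smoothing of a gaze trace.

    Each output point is a weighted mean of the neighbouring samples with
    Gaussian weights in time (scale ``bilateral_time_ms``) and in Euclidean
    screen distance (scale ``bilateral_space_px``); the spatial term keeps
    genuine steps (saccades) sharper than a plain temporal Gaussian would.
    Support is truncated at +-3 temporal sigma.  Timestamps and trace
    length are unchanged; constant traces are fixed points.
    """
    t, xy = trace_to_arrays(trace)
    _check_sorted(t)
    sig_t = cfg.bilateral_time_ms / 1000.0
    sig_s = cfg.bilateral_space_px
    out = np.empty_like(xy)
    lo = np.searchsorted(t, t - 3 * sig_t, side="left")
    hi = np.searchsorted(t, t + 3 * sig_t, side="right")
    for i in range(len(t)):
        sl = slice(lo[i], hi[i])
        dt = t[sl] - t[i]
        ds = np.linalg.norm(xy[sl] - xy[i], axis=1)
        w = np.exp(-0.5 * (dt / sig_t) ** 2 - 0.5 * (ds / sig_s) ** 2)
        out[i] = (w[:, None] * xy[sl]).sum(axis=0) / w.sum()
    return arrays_to_trace(t, out, Stage.SMOOTHED)


def _angular_velocity(t: np.ndarray, xy: np.ndarray, g: ScreenGeometry) -> np.ndarray:
    """Instantaneous angular speed (deg/s), central difference inside,
    one-sided at the boundaries.  Displacement chords are converted to
    degrees via atan(chord_cm / distance)."""
    n = len(t)
    v = np.zeros(n)
    for i in range(n):
        j0 = max(i - 1, 0)
        j1 = min(i + 1, n - 1)
        dt = t[j1] - t[j0]
        if dt <= 0:
            v[i] = 0.0
            continue
        chord_cm = float(np.linalg.norm(xy[j1] - xy[j0])) / g.px_per_cm
        v[i] = cm_to_degrees(chord_cm, g.viewing_distance_cm) / dt
    return v


def classify_ivt(trace: Sequence[GazeSample], cfg: EventConfig, g: ScreenGeometry) -> np.ndarray:
    """Per-sample I-VT labels: True = saccade, False = fixation.

    A sample is a saccade iff its angular velocity is at or above the
    threshold (equality counts as saccade).
    """
    if len(trace) < 2:
        raise ValueError("need at least 2 samples to classify")
    t, xy = trace_to_arrays(trace)
    _check_sorted(t)
    v = _angular_velocity(t, xy, g)
    return v >= cfg.velocity_threshold_deg_s


def _runs(labels: np.ndarray, t: np.ndarray, max_gap_s: float):
    """Yield (value, start_idx, end_idx) runs, split at temporal gaps."""
    start = 0
    for i in range(1, len(labels) + 1):
        if (i == len(labels) or labels[i] != labels[start]
                or t[i] - t[i - 1] > max_gap_s):
            yield bool(labels[start]), start, i - 1
            start = i


def extract_events(labels: np.ndarray, trace: Sequence[GazeSample],
                   cfg: EventConfig = EventConfig(),
                   g: Optional[ScreenGeometry] = None) -> List[OculomotorEvent]:
    """Merge per-sample labels into non-overlapping fixation/saccade events.

    Fixations are maximal fixation-labeled runs with centroid = mean
    position; runs shorter than ``min_fixation_ms`` are dropped.  Saccade
    spans are padded to the midpoints between their boundary samples and
    the adjacent samples so that events never overlap.  Saccade amplitude
    is measured between the surrounding fixation centroids when both
    exist, otherwise between the saccade's boundary samples (requires
    ``g`` for the degree conversion; omitted if ``g`` is None).
    """
    t, xy = trace_to_arrays(trace)
    if len(labels) != len(t):
        raise ValueError("labels must align with trace")
    raw = list(_runs(np.asarray(labels, dtype=bool), t, cfg.max_gap_ms / 1000.0))
    events: List[OculomotorEvent] = []
    fix_centroids = {}
    max_gap_s = cfg.max_gap_ms / 1000.0
    for k, (is_sacc, i0, i1) in enumerate(raw):
        if not is_sacc:
            dur_ms = (t[i1] - t[i0]) * 1000.0  # raw run span decides the cut
            if dur_ms >= cfg.min_fixation_ms:
                c = xy[i0 : i1 + 1].mean(axis=0)
                fix_centroids[k] = c
                # pad to the midpoints toward adjacent samples (the sample
                # grid quantizes boundaries; the true transition lies
                # between samples), except across gaps or trace edges
                onset = float(t[i0])
                if i0 > 0 and t[i0] - t[i0 - 1] <= max_gap_s:
                    onset = float((t[i0] + t[i0 - 1]) / 2)
                offset = float(t[i1])
                if i1 < len(t) - 1 and t[i1 + 1] - t[i1] <= max_gap_s:
                    offset = float((t[i1] + t[i1 + 1]) / 2)
                events.append(OculomotorEvent("fixation", onset, offset,
                                              centroid=(float(c[0]), float(c[1]))))
    for k, (is_sacc, i0, i1) in enumerate(raw):
        if not is_sacc:
            continue
        dt_before = t[i0] - t[i0 - 1] if i0 > 0 else (t[1] - t[0] if len(t) > 1 else 1 / 30)
        dt_after = t[i1 + 1] - t[i1] if i1 < len(t) - 1 else dt_before
        # same midpoint padding as fixations, skipped across gaps
        onset = float(t[i0] - dt_before / 2) if dt_before <= max_gap_s else float(t[i0])
        offset = float(t[i1] + dt_after / 2) if dt_after <= max_gap_s else float(t[i1])
        p0 = fix_centroids.get(k - 1, xy[i0])
        p1 = fix_centroids.get(k + 1, xy[i1])
        amp = None
        if g is not None:
            amp = cm_to_degrees(float(np.linalg.norm(np.asarray(p1) - np.asarray(p0)))
                                / g.px_per_cm, g.viewing_distance_cm)
        if offset > onset:
            events.append(OculomotorEvent("saccade", onset, offset, amplitude_deg=amp))
    events.sort(key=lambda e: e.onset)
    return events


def extract_fixations(labels: np.ndarray, trace: Sequence[GazeSample],
                      cfg: EventConfig = EventConfig()) -> List[OculomotorEvent]:
    """Fixation events only (see :func:`extract_events`)."""
    return [e for e in extract_events(labels, trace, cfg) if e.kind == "fixation"]


def saccade_latency(trace: Sequence[GazeSample], stimulus_onset: float,
                    cfg: EventConfig, g: ScreenGeometry) -> Optional[float]:
    """Milliseconds from stimulus onset to the first saccade-labeled sample.

    Returns None (missing) when no saccade follows the onset — never zero.
    """
    t, _ = trace_to_arrays(trace)
    if not (t[0] <= stimulus_onset <= t[-1]):
        raise ValueError("stimulus onset outside trace span")
    labels = classify_ivt(trace, cfg, g)
    after = np.where((t >= stimulus_onset) & labels)[0]
    if len(after) == 0:
        return None
    return float((t[after[0]] - stimulus_onset) * 1000.0)


def aggregate_per_stimulus(trace: Sequence[GazeSample],
                           stimulus_intervals: Sequence[Tuple[float, float]],
                           cfg: EventConfig, g: ScreenGeometry) -> List[Optional[np.ndarray]]:
    """One aggregate gaze point per stimulus interval.

    For each interval the first ``onset_discard_ms`` of samples are
    discarded (allowing the eye to land on the stimulus), remaining
    estimates are snapped onto the screen, and the componentwise median is
    returned.  An interval fully consumed by the discard yields None.
    """
    ivs = sorted(stimulus_intervals)
    for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
        if b0 < a1:
            raise ValueError("stimulus intervals must be non-overlapping")
    t, xy = trace_to_arrays(trace)
    _check_sorted(t)
    out: List[Optional[np.ndarray]] = []
    for t0, t1 in stimulus_intervals:
        keep = (t >= t0 + cfg.onset_discard_ms / 1000.0) & (t <= t1)
        if not np.any(keep):
            out.append(None)
            continue
        snapped = snap_to_screen(xy[keep], g)
        out.append(np.median(snapped, axis=0))
    return out
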