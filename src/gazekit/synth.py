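"""Synthetic data generators: rendered eye frames and simulated scanpaths.

Everything downstream is testable without any external dataset because
the generators emit machine-readable ground truth next to every fixture.

* :func:`render_eye_frame` draws a stylised face strip (two bright
  eyeballs on a dark background) in which each iris is displaced from its
  eye centre **linearly** in the on-screen gaze position, plus a constant
  per-user bias — a deliberately simple appearance model that makes the
  gaze-estimation problem solvable by the small network at desk scale
  while exercising the full crop/landmark/training pipeline.
* :func:`simulate_scanpath` produces 30 Hz gaze traces for the task
  protocols: stationary fixations with jitter, minimum-jerk saccades
  (super-threshold mid-flight velocity, so I-VT ground truth is well
  defined), pursuit that trails the target by a configurable lag, and a
  detection-probability searcher whose chance of spotting the target per
  fixation grows with target contrast.
* :func:`make_calibration_session` renders dot or zig-zag calibration
  sessions (~30 s at 30 Hz by default) for personalization experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .events import OculomotorEvent
from .geometry import GazeSample, ScreenGeometry, Stage, cm_to_degrees
from .network import EyeFrame
from .personalization import CalibrationRecord
from .protocols import ProsaccadeTrial, PursuitPath, SearchDisplay
from .reading import PassageRegion, TaskOutcome

__all__ = [
    "default_geometry",
    "SyntheticEyeParams",
    "ScanpathParams",
    "SimulatedScanpath",
    "render_eye_frame",
    "simulate_scanpath",
    "make_calibration_session",
    "make_user",
    "make_base_training_set",
    "simulate_reading_task",
    "simulate_reading_cohort",
]


def default_geometry() -> ScreenGeometry:
    """The synthetic study device: 1440 x 2880 portrait screen, 180 px/cm
    (8 x 16 cm), viewed at 30 cm."""
    return ScreenGeometry(width_px=1440, height_px=2880, px_per_cm=180.0,
                          viewing_distance_cm=30.0)


# frame layout constants (px): two eyes on one horizontal line
_FRAME_W, _FRAME_H = 256, 160
_EYE_Y = 80.0
_LEFT_CORNERS = ((40.0, _EYE_Y), (104.0, _EYE_Y))
_RIGHT_CORNERS = ((152.0, _EYE_Y), (216.0, _EYE_Y))


@dataclass(frozen=True)
class SyntheticEyeParams:
    """Appearance parameters of a synthetic user."""

    eyeball_radius_px: float = 30.0
    iris_radius_px: float = 11.0
    gaze_to_iris_gain: float = 1.7  # iris px per screen cm of gaze offset
    noise_sd: float = 0.02  # additive pixel noise (intensity units)
    per_user_bias_cm: Tuple[float, float] = (0.0, 0.0)
    fixation_jitter_cm: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eyeball_radius_px <= 0 or self.iris_radius_px <= 0:
            raise ValueError("radii must be positive")
        if self.gaze_to_iris_gain <= 0:
            raise ValueError("gain must be positive")


def make_user(seed: int, bias_sd_cm: float = 0.8,
              base: SyntheticEyeParams = SyntheticEyeParams()) -> SyntheticEyeParams:
    """A synthetic participant: the base appearance plus a random constant
    gaze bias drawn N(0, ``bias_sd_cm``) per coordinate."""
    rng = np.random.default_rng(seed)
    bias = tuple(np.clip(rng.normal(0.0, bias_sd_cm, size=2), -2.0, 2.0))
    return replace(base, per_user_bias_cm=(float(bias[0]), float(bias[1])), seed=seed)


def _disk(img: np.ndarray, center: Tuple[float, float], radius: float, value: float) -> None:
    """Paint an anti-aliased disk (1 px soft edge) onto a 2-D canvas."""
    H, W = img.shape
    x0 = max(int(center[0] - radius) - 2, 0)
    x1 = min(int(center[0] + radius) + 3, W)
    y0 = max(int(center[1] - radius) - 2, 0)
    y1 = min(int(center[1] + radius) + 3, H)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    d = np.sqrt((xs - center[0]) ** 2 + (ys - center[1]) ** 2)
    alpha = np.clip(radius - d + 0.5, 0.0, 1.0)
    img[y0:y1, x0:x1] = img[y0:y1, x0:x1] * (1 - alpha) + value * alpha


def render_eye_frame(gaze_cm: Sequence[float], params: SyntheticEyeParams,
                     g: ScreenGeometry, t: float = 0.0,
                     rng: Optional[np.random.Generator] = None
                     ) -> Tuple[EyeFrame, Dict[str, np.ndarray]]:
    """Render one synthetic camera frame for a known gaze point (cm).

    Both irises are displaced from their eye centres by
    ``gain * (gaze - screen_center + bias)`` px.  Returns the frame and a
    ground-truth dict with the iris displacement and the biased gaze the
    frame actually encodes.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    gaze_cm = np.asarray(gaze_cm, dtype=float)
    center_cm = np.array([g.width_cm / 2.0, g.height_cm / 2.0])
    bias = np.asarray(params.per_user_bias_cm)
    disp = params.gaze_to_iris_gain * (gaze_cm - center_cm + bias)
    if np.linalg.norm(disp) > params.eyeball_radius_px - params.iris_radius_px:
        raise ValueError("gain drives iris outside the eyeball")
    canvas = np.full((_FRAME_H, _FRAME_W), 0.20, dtype=np.float32)
    for corners in (_LEFT_CORNERS, _RIGHT_CORNERS):
        eye_center = np.asarray(corners).mean(axis=0)
        _disk(canvas, tuple(eye_center), params.eyeball_radius_px, 0.95)
        _disk(canvas, tuple(eye_center + disp), params.iris_radius_px, 0.10)
    if params.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, params.noise_sd, canvas.shape).astype(np.float32)
    canvas = np.clip(canvas, 0.0, 1.0)
    image = np.repeat(canvas[:, :, None], 3, axis=2)
    landmarks = np.array(_LEFT_CORNERS + _RIGHT_CORNERS, dtype=float)
    frame = EyeFrame(image=image, landmarks=landmarks, t=t)
    truth = {"iris_displacement_px": disp, "encoded_gaze_cm": gaze_cm + bias}
    return frame, truth


def _zigzag_marker(frac: float, g: ScreenGeometry, n_rows: int = 6,
                   margin: float = 0.08) -> np.ndarray:
    x0, x1 = margin * g.width_px, (1 - margin) * g.width_px
    y0, y1 = margin * g.height_px, (1 - margin) * g.height_px
    saw = frac * n_rows % 2.0
    xf = saw if saw <= 1.0 else 2.0 - saw
    return np.array([x0 + xf * (x1 - x0), y0 + frac * (y1 - y0)])


def make_calibration_session(n_frames: int = 900, layout: str = "dot",
                             user: SyntheticEyeParams = SyntheticEyeParams(),
                             g: Optional[ScreenGeometry] = None,
                             seed: int = 0, n_markers: int = 30,
                             rate_hz: float = 30.0,
                             session_id: str = "s0") -> List[CalibrationRecord]:
    """Render a calibration session (~30 s at 30 Hz by default).

    ``dot`` shows ``n_markers`` random on-screen markers for equal runs of
    frames; ``zigzag`` sweeps the marker from top-left to bottom-right.
    The rendered gaze is the marker plus fixation jitter; the user's bias
    enters only through the renderer.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if g is None:
        g = default_geometry()
    rng = np.random.default_rng(seed)
    margin = 0.06
    if layout == "dot":
        markers = np.stack([
            rng.uniform(margin * g.width_px, (1 - margin) * g.width_px, n_markers),
            rng.uniform(margin * g.height_px, (1 - margin) * g.height_px, n_markers),
        ], axis=1)
        per = max(n_frames // n_markers, 1)
        marker_of = lambda i: markers[min(i // per, n_markers - 1)]
    elif layout == "zigzag":
        marker_of = lambda i: _zigzag_marker(i / max(n_frames - 1, 1), g)
    else:
        raise ValueError(f"unknown layout: {layout}")
    records = []
    for i in range(n_frames):
        marker_px = np.asarray(marker_of(i), dtype=float)
        jitter_cm = rng.normal(0.0, user.fixation_jitter_cm, size=2)
        gaze_cm = marker_px / g.px_per_cm + jitter_cm
        frame, _ = render_eye_frame(gaze_cm, user, g, t=i / rate_hz, rng=rng)
        records.append(CalibrationRecord(frame=frame, marker=marker_px,
                                         session_id=session_id))
    return records


def make_base_training_set(n_users: int = 20, frames_per_user: int = 60,
                           g: Optional[ScreenGeometry] = None, seed: int = 0,
                           bias_sd_cm: float = 0.8
                           ) -> Tuple[List[Tuple[EyeFrame, np.ndarray]], List[SyntheticEyeParams]]:
    """Pooled (frame, target-px) training set over synthetic users."""
    if g is None:
        g = default_geometry()
    dataset, users = [], []
    for u in range(n_users):
        user = make_user(seed * 1000 + u, bias_sd_cm=bias_sd_cm)
        users.append(user)
        recs = make_calibration_session(frames_per_user, "dot", user, g,
                                        seed=seed * 1000 + u,
                                        n_markers=max(frames_per_user // 3, 2),
                                        session_id=f"user{u}")
        dataset.extend((r.frame, r.marker) for r in recs)
    return dataset, users


# ---------------------------------------------------------------------------
# scanpath simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanpathParams:
    """Generative settings for simulated gaze traces.

    Fixation durations are log-normal (median ~280 ms); prosaccade
    latencies are a shifted gamma with mean 210 ms; the pursuit eye trails
    the target by ``pursuit_lag_ms``; traces are sampled at 30 Hz with
    additive Gaussian position noise.
    """

    fixation_log_mean: float = math.log(0.28)
    fixation_log_sd: float = 0.35
    saccade_latency_mean_s: float = 0.210
    saccade_latency_shift_s: float = 0.080
    saccade_latency_shape: float = 4.0
    pursuit_lag_ms: float = 100.0
    sample_rate_hz: float = 30.0
    noise_sd_px: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")
        if self.saccade_latency_mean_s <= self.saccade_latency_shift_s:
            raise ValueError("latency mean must exceed its shift")


@dataclass(frozen=True)
class SimulatedScanpath:
    trace: List[GazeSample]
    events: List[OculomotorEvent]
    truth: Dict


def _draw_latency(params: ScanpathParams, rng: np.random.Generator) -> float:
    scale = (params.saccade_latency_mean_s - params.saccade_latency_shift_s) / params.saccade_latency_shape
    return params.saccade_latency_shift_s + rng.gamma(params.saccade_latency_shape, scale)


def _draw_fix_duration(params: ScanpathParams, rng: np.random.Generator) -> float:
    return float(rng.lognormal(params.fixation_log_mean, params.fixation_log_sd))


def _saccade_duration_s(amplitude_deg: float) -> float:
    """Main-sequence-style duration: ~21 ms + 2.2 ms per degree."""
    return 0.021 + 0.0022 * amplitude_deg


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5


def _fixation_sequence_trace(points: Sequence[np.ndarray], durations: Sequence[float],
                             params: ScanpathParams, g: ScreenGeometry,
                             rng: np.random.Generator, t0: float = 0.0):
    """Continuous fixation/saccade position profile sampled at the frame
    rate; returns (trace, ground-truth events)."""
    segments = []  # (t_start, t_end, kind, p0, p1)
    events: List[OculomotorEvent] = []
    t = t0
    for i, (p, d) in enumerate(zip(points, durations)):
        events.append(OculomotorEvent("fixation", t, t + d,
                                      centroid=(float(p[0]), float(p[1]))))
        segments.append((t, t + d, "fix", p, p))
        t += d
        if i + 1 < len(points):
            p_next = points[i + 1]
            amp_deg = cm_to_degrees(float(np.linalg.norm(p_next - p)) / g.px_per_cm,
                                    g.viewing_distance_cm)
            sd = _saccade_duration_s(amp_deg)
            events.append(OculomotorEvent("saccade", t, t + sd, amplitude_deg=amp_deg))
            segments.append((t, t + sd, "sacc", p, p_next))
            t += sd
    n = int(math.floor((t - t0) * params.sample_rate_hz)) + 1
    ts = t0 + np.arange(n) / params.sample_rate_hz
    xy = np.empty((n, 2))
    si = 0
    for k, tk in enumerate(ts):
        while si < len(segments) - 1 and tk >= segments[si][1]:
            si += 1
        s0, s1, kind, p0, p1 = segments[si]
        if kind == "fix":
            xy[k] = p0
        else:
            tau = np.clip((tk - s0) / (s1 - s0), 0.0, 1.0)
            xy[k] = p0 + (p1 - p0) * _minimum_jerk(np.array([tau]))[0]
    xy = xy + rng.normal(0.0, params.noise_sd_px, xy.shape)
    trace = [GazeSample(float(tt), float(p[0]), float(p[1]), Stage.RAW)
             for tt, p in zip(ts, xy)]
    return trace, events


def _searcher_item_sequence(display: SearchDisplay, params: ScanpathParams,
                            rng: np.random.Generator) -> List[int]:
    """Guided-search fixation sequence.

    Before every fixation the target may pop out (probability grows with
    its feature contrast); otherwise the searcher serially fixates a
    random unvisited item and recognises the target whenever it lands on
    it.  High contrast therefore ends search in ~1 fixation regardless of
    set size, while low contrast degenerates to a serial scan whose
    length grows with the number of items."""
    if display.mode == "orientation":
        p_popout = 1.0 / (1.0 + math.exp(-(display.contrast - 10.0) / 2.5))
    else:
        p_popout = 1.0 / (1.0 + math.exp(-(display.contrast - 0.12) / 0.03))
    target_idx = next(i for i, it in enumerate(display.items) if it.is_target)
    unvisited = list(range(display.set_size))
    seq: List[int] = []
    while True:
        if rng.random() < p_popout:
            seq.append(target_idx)
            return seq
        if not unvisited:  # exhaustive pass missed nothing; rescan
            unvisited = [i for i in range(display.set_size) if i != target_idx]
        j = unvisited.pop(int(rng.integers(len(unvisited))))
        seq.append(j)
        if j == target_idx:
            return seq


def simulate_scanpath(protocol: Union[ProsaccadeTrial, PursuitPath, SearchDisplay, dict],
                      params: ScanpathParams,
                      g: Optional[ScreenGeometry] = None,
                      rng: Optional[np.random.Generator] = None) -> SimulatedScanpath:
    """Simulate a gaze trace (plus ground truth) for a task protocol."""
    if g is None:
        g = default_geometry()
    if rng is None:
        rng = np.random.default_rng(params.seed)

    if isinstance(protocol, ProsaccadeTrial):
        latency = _draw_latency(params, rng)
        onset = protocol.stimulus_onset_s
        total = protocol.total_duration_s
        if onset + latency >= total:
            latency = max(total - onset - 0.1, 0.05)
        center = g.center_px
        target = np.asarray(protocol.target, dtype=float)
        points = [center, target]
        durations = [onset + latency, total - onset - latency]
        trace, events = _fixation_sequence_trace(points, durations, params, g, rng)
        return SimulatedScanpath(trace, events,
                                 {"latency_ms": latency * 1000.0,
                                  "stimulus_onset_s": onset})

    if isinstance(protocol, PursuitPath):
        lag = params.pursuit_lag_ms / 1000.0
        ts = np.arange(int(protocol.duration_s * params.sample_rate_hz) + 1) / params.sample_rate_hz
        ts = ts + protocol.t[0]
        lagged = np.clip(ts - lag, protocol.t[0], protocol.t[-1])
        xy = protocol.at(lagged)
        xy = xy + rng.normal(0.0, params.noise_sd_px, xy.shape)
        trace = [GazeSample(float(t), float(p[0]), float(p[1]), Stage.RAW)
                 for t, p in zip(ts, xy)]
        return SimulatedScanpath(trace, [], {"lag_ms": params.pursuit_lag_ms})

    if isinstance(protocol, SearchDisplay):
        seq = _searcher_item_sequence(protocol, params, rng)
        pts = [np.asarray(protocol.items[j].position) + rng.normal(0, 15.0, 2)
               for j in seq]
        durs = [_draw_fix_duration(params, rng) for _ in seq]
        trace, events = _fixation_sequence_trace(pts, durs, params, g, rng)
        return SimulatedScanpath(trace, events,
                                 {"n_fixations_to_target": len(seq),
                                  "item_sequence": seq})

    if isinstance(protocol, dict) and protocol.get("kind") == "fixations":
        pts = [np.asarray(p, dtype=float) for p in protocol["points"]]
        durs = list(protocol.get("durations")
                    or [_draw_fix_duration(params, rng) for _ in pts])
        if len(durs) != len(pts):
            raise ValueError("durations must match points")
        trace, events = _fixation_sequence_trace(pts, durs, params, g, rng)
        return SimulatedScanpath(trace, events, {"n_fixations": len(pts)})

    raise ValueError(f"unsupported protocol: {protocol!r}")


# ---------------------------------------------------------------------------
# reading comprehension cohort
# ---------------------------------------------------------------------------

def simulate_reading_task(task_id: str, difficulty_pct: float,
                          regions: Sequence[PassageRegion],
                          rng: np.random.Generator,
                          n_participants: int = 10,
                          n_fixations: int = 60,
                          page_width_px: float = 1440.0
                          ) -> Tuple[List[OculomotorEvent], List[TaskOutcome]]:
    """One synthetic reading task.

    The generative link mirrors the hypothesis under test: the target
    height-normalized relevant-dwell share decreases with task difficulty
    (80% at difficulty 0 down toward chance), and answers are wrong with
    probability ``difficulty_pct``/100.
    """
    rel_regions = [r for r in regions if r.label == "relevant"]
    irr_regions = [r for r in regions if r.label == "irrelevant"]
    h_rel = sum(r.height for r in rel_regions)
    h_irr = sum(r.height for r in irr_regions)
    h_tot = h_rel + h_irr
    target_share = float(np.clip(80.0 - 0.55 * difficulty_pct + rng.normal(0, 3.0), 5.0, 95.0))
    q = target_share / 100.0
    # dwell-time share that yields the target density share
    w = q * (h_rel / h_tot) / (q * (h_rel / h_tot) + (1 - q) * (h_irr / h_tot))
    fixations: List[OculomotorEvent] = []
    t = 0.0
    for _ in range(n_fixations):
        dur = float(rng.lognormal(math.log(0.28), 0.35))
        if rng.random() < w:
            reg = rel_regions[int(rng.integers(len(rel_regions)))]
        else:
            reg = irr_regions[int(rng.integers(len(irr_regions)))]
        y = float(rng.uniform(reg.y_top, reg.y_bottom))
        x = float(rng.uniform(0.1 * page_width_px, 0.9 * page_width_px))
        fixations.append(OculomotorEvent("fixation", t, t + dur, centroid=(x, y)))
        t += dur + 0.04
    outcomes = [TaskOutcome(task_id, "factual",
                            correct=bool(rng.random() >= difficulty_pct / 100.0),
                            time_to_answer_s=float(20 + 0.4 * difficulty_pct
                                                   + rng.exponential(5.0)))
                for _ in range(n_participants)]
    return fixations, outcomes


def simulate_reading_cohort(n_tasks: int = 10, seed: int = 0,
                            page_height_px: float = 6000.0):
    """A cohort of reading tasks spanning easy to hard.

    Returns ``(per_task_fixations, per_task_regions, outcomes)`` keyed by
    task id.
    """
    rng = np.random.default_rng(seed)
    difficulties = np.linspace(0.0, 60.0, n_tasks)
    fixmap, regmap, outcomes = {}, {}, []
    for i, d in enumerate(difficulties):
        tid = f"task{i}"
        top = float(rng.uniform(0.15, 0.65)) * page_height_px
        height = float(rng.uniform(0.12, 0.25)) * page_height_px
        regions = [
            PassageRegion("irrelevant", 0.0, top),
            PassageRegion("relevant", top, top + height),
            PassageRegion("irrelevant", top + height, page_height_px),
        ]
        fx, oc = simulate_reading_task(tid, float(d), regions, rng)
        fixmap[tid], regmap[tid] = fx, regions
        outcomes.extend(oc)
    return fixmap, regmap, outcomes
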