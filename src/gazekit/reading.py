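"""Reading-comprehension gaze analytics.

Passages longer than the screen are read by scrolling, so screen-space
gaze must first be synchronised with a viewport (scroll) log to obtain
page-level coordinates.  On the page, the passage body is partitioned
into labelled regions (the relevant excerpt containing a factual answer
vs the irrelevant remainder) and gaze is summarised as a height-normalized
dwell share: the fraction of fixation time per region divided by the
region's share of the page height, renormalised across labels to sum to
100%.  Under uniform reading every label scores its even share; values
above 100/n_labels % mean disproportionate attention.

Task difficulty is the percentage of incorrect answers per task; its
association with gaze metrics is measured by Spearman rank correlation
with a seeded permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import spearmanr

from .events import OculomotorEvent
from .geometry import GazeSample, Stage

__all__ = [
    "ViewportLog",
    "PassageRegion",
    "TaskOutcome",
    "to_page_coords",
    "project_to_screen",
    "region_dwell_fraction",
    "task_difficulty",
    "difficulty_correlates",
]


@dataclass(frozen=True)
class ViewportLog:
    """Event-driven scroll log: the offset holds until the next entry."""

    t: np.ndarray  # entry times, seconds, sorted
    scroll_offset_px: np.ndarray  # page y of the viewport top
    page_height_px: float
    viewport_height_px: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        off = np.asarray(self.scroll_offset_px, dtype=float)
        if t.ndim != 1 or t.shape != off.shape or len(t) == 0:
            raise ValueError("log needs matching 1-D time/offset arrays")
        if np.any(np.diff(t) < 0):
            raise ValueError("log entries must be time-sorted")
        max_off = self.page_height_px - self.viewport_height_px
        if np.any(off < 0) or np.any(off > max_off + 1e-9):
            raise ValueError("offsets must lie within [0, page - viewport]")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "scroll_offset_px", off)

    def offset_at(self, times) -> np.ndarray:
        """Step interpolation: the last entry at or before each time."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.searchsorted(self.t, times, side="right") - 1
        if np.any(idx < 0):
            raise ValueError("time precedes the first viewport entry")
        return self.scroll_offset_px[idx]


def to_page_coords(trace: Sequence[GazeSample], log: ViewportLog) -> List[GazeSample]:
    """Map screen-space gaze onto page coordinates using the scroll log.

    ``page_y = screen_y + scroll_offset(t)``; x is unchanged.  Samples
    before the first log entry are rejected.
    """
    t = np.array([s.t for s in trace])
    offs = log.offset_at(t)
    return [GazeSample(s.t, s.x, s.y + float(o), s.stage) for s, o in zip(trace, offs)]


def project_to_screen(page_trace: Sequence[GazeSample], log: ViewportLog,
                      clip: bool = True) -> List[GazeSample]:
    """Inverse projection (page to screen) used by the simulator.

    With ``clip`` set, samples falling outside the viewport are dropped
    (the reader cannot look at content that is not on screen).
    """
    out = []
    for s in page_trace:
        off = float(log.offset_at(s.t)[0])
        sy = s.y - off
        if clip and not (0 <= sy <= log.viewport_height_px):
            continue
        out.append(GazeSample(s.t, s.x, sy, s.stage))
    return out


@dataclass(frozen=True)
class PassageRegion:
    label: str  # relevant | irrelevant
    y_top: float
    y_bottom: float

    def __post_init__(self) -> None:
        if not self.y_bottom > self.y_top:
            raise ValueError("y_bottom must exceed y_top")

    @property
    def height(self) -> float:
        return self.y_bottom - self.y_top


def _check_partition(regions: Sequence[PassageRegion]) -> None:
    rs = sorted(regions, key=lambda r: r.y_top)
    for a, b in zip(rs, rs[1:]):
        if b.y_top < a.y_bottom - 1e-9:
            raise ValueError("regions must not overlap")


def region_dwell_fraction(fixations: Sequence[OculomotorEvent],
                          regions: Sequence[PassageRegion]) -> Dict[str, float]:
    """Height-normalized dwell percentage per region label.

    For each label, dwell density = (share of total fixation duration on
    that label's regions) / (share of passage height).  Densities are
    renormalised across labels to percentages summing to 100.  A fixation
    is assigned to the region containing its centroid y; fixations outside
    every region are ignored.
    """
    _check_partition(regions)
    dwell: Dict[str, float] = {}
    height: Dict[str, float] = {}
    for r in regions:
        height[r.label] = height.get(r.label, 0.0) + r.height
    for f in fixations:
        if f.kind != "fixation":
            continue
        y = f.centroid[1]
        for r in regions:
            if r.y_top <= y < r.y_bottom:
                dwell[r.label] = dwell.get(r.label, 0.0) + f.duration
                break
    total_dwell = sum(dwell.values())
    if total_dwell <= 0:
        raise ValueError("zero total fixation time within the regions")
    total_height = sum(height.values())
    density = {lab: (dwell.get(lab, 0.0) / total_dwell) / (h / total_height)
               for lab, h in height.items()}
    z = sum(density.values())
    return {lab: 100.0 * d / z for lab, d in density.items()}


@dataclass(frozen=True)
class TaskOutcome:
    task_id: str
    kind: str  # factual | interpretive
    correct: bool
    time_to_answer_s: float

    def __post_init__(self) -> None:
        if self.time_to_answer_s <= 0:
            raise ValueError("time_to_answer_s must be positive")
        if self.kind not in ("factual", "interpretive"):
            raise ValueError("kind must be 'factual' or 'interpretive'")


def task_difficulty(outcomes: Sequence[TaskOutcome]) -> Dict[str, float]:
    """Percent incorrect answers per task."""
    n: Dict[str, int] = {}
    wrong: Dict[str, int] = {}
    for o in outcomes:
        n[o.task_id] = n.get(o.task_id, 0) + 1
        wrong[o.task_id] = wrong.get(o.task_id, 0) + (not o.correct)
    return {tid: 100.0 * wrong[tid] / n[tid] for tid in n}


def difficulty_correlates(per_task_metric: Mapping[str, float],
                          difficulty: Mapping[str, float],
                          n_permutations: int = 10000,
                          seed: int = 0) -> Tuple[float, float]:
    """Spearman rank correlation between a gaze metric and task difficulty.

    Ties receive average ranks.  Significance is a two-sided permutation
    test with seeded shuffles of the difficulty vector.  Returns
    ``(rho, p)``.
    """
    tasks = sorted(set(per_task_metric) & set(difficulty))
    if len(tasks) < 4:
        raise ValueError("need at least 4 tasks")
    x = np.array([per_task_metric[t] for t in tasks])
    y = np.array([difficulty[t] for t in tasks])
    rho = float(spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        r = float(spearmanr(x, rng.permutation(y)).statistic)
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return rho, float(p)
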