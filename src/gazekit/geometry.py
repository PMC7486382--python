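"""Screen geometry and unit conversions.

All modules share one coordinate convention: origin at the top-left of the
screen, x increasing rightward, y increasing downward, units of screen
pixels, phone held in portrait mode (height >= width).  A
:class:`ScreenGeometry` instance is the sole authority for converting
between pixels, centimetres on the screen surface, and visual degrees at
the viewer's eye.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ScreenGeometry",
    "GazeSample",
    "Stage",
    "ErrorReport",
    "px_to_cm",
    "cm_to_px",
    "cm_to_degrees",
    "degrees_to_cm",
    "snap_to_screen",
]

#: Midpoint of the 25-40 cm comfortable phone viewing range; used when a
#: trace carries no distance metadata.
DEFAULT_VIEWING_DISTANCE_CM = 30.0


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical description of a phone screen in portrait orientation.

    Parameters
    ----------
    width_px, height_px : int
        Screen size in pixels; portrait convention requires
        ``height_px >= width_px``.
    px_per_cm : float
        Pixel density of the display.  Device specific, hence required —
        there is no hardcoded device table.
    viewing_distance_cm : float
        Distance from the eye to the screen, used for degree conversions.
    """

    width_px: int
    height_px: int
    px_per_cm: float
    viewing_distance_cm: float = DEFAULT_VIEWING_DISTANCE_CM

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("screen dimensions must be positive")
        if self.height_px < self.width_px:
            raise ValueError("portrait convention requires height_px >= width_px")
        if not (self.px_per_cm > 0 and math.isfinite(self.px_per_cm)):
            raise ValueError("px_per_cm must be positive and finite")
        if not (self.viewing_distance_cm > 0 and math.isfinite(self.viewing_distance_cm)):
            raise ValueError("viewing_distance_cm must be positive and finite")

    @property
    def width_cm(self) -> float:
        return self.width_px / self.px_per_cm

    @property
    def height_cm(self) -> float:
        return self.height_px / self.px_per_cm

    @property
    def center_px(self) -> np.ndarray:
        return np.array([self.width_px / 2.0, self.height_px / 2.0])

    # -- px <-> cm -----------------------------------------------------
    def px_to_cm(self, p) -> np.ndarray:
        return px_to_cm(p, self)

    def cm_to_px(self, p) -> np.ndarray:
        return cm_to_px(p, self)

    # -- degrees -------------------------------------------------------
    def px_to_degrees(self, extent_px: float) -> float:
        """Visual angle subtended by an on-screen extent given in pixels."""
        return cm_to_degrees(extent_px / self.px_per_cm, self.viewing_distance_cm)

    def degrees_to_px(self, angle_deg: float) -> float:
        return degrees_to_cm(angle_deg, self.viewing_distance_cm) * self.px_per_cm


class Stage(str, Enum):
    """Provenance of a gaze sample within the pipeline."""

    RAW = "raw"
    SMOOTHED = "smoothed"
    PERSONALIZED = "personalized"


@dataclass(frozen=True)
class GazeSample:
    """A timestamped on-screen point of regard.

    Coordinates may lie off-screen: snapping to the valid screen area is an
    explicit downstream step, never implicit.
    """

    t: float
    x: float
    y: float
    stage: Stage = Stage.RAW

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t) and math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("gaze sample fields must be finite")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class ErrorReport:
    """Per-target calibration errors in cm plus degree equivalents."""

    per_target_error_cm: tuple
    error_deg_at: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        errs = tuple(float(e) for e in self.per_target_error_cm)
        if any(e < 0 or not math.isfinite(e) for e in errs):
            raise ValueError("errors must be finite and nonnegative")
        object.__setattr__(self, "per_target_error_cm", errs)

    @property
    def mean_error_cm(self) -> float:
        return float(np.mean(self.per_target_error_cm))

    @classmethod
    def from_errors(
        cls, errors_cm: Sequence[float], viewing_distances_cm: Sequence[float] = (25.0, 40.0)
    ) -> "ErrorReport":
        errs = tuple(float(e) for e in errors_cm)
        mean = float(np.mean(errs)) if errs else 0.0
        degs = {d: cm_to_degrees(mean, d) for d in viewing_distances_cm}
        return cls(per_target_error_cm=errs, error_deg_at=degs)


def _as_point(p) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite coordinates")
    return arr


def px_to_cm(p, g: ScreenGeometry) -> np.ndarray:
    """Convert point(s) from screen pixels to cm (same origin, y-down)."""
    return _as_point(p) / g.px_per_cm


def cm_to_px(p, g: ScreenGeometry) -> np.ndarray:
    """Inverse of :func:`px_to_cm`."""
    return _as_point(p) * g.px_per_cm


def cm_to_degrees(extent_cm: float, distance_cm: float) -> float:
    """Visual angle in degrees subtended by ``extent_cm`` at ``distance_cm``.

    Uses the full-extent convention ``atan(extent / distance)``, under which
    a 0.46 cm error at 25-40 cm viewing distance maps to roughly 0.66-1.05
    degrees of visual angle.
    """
    if not (distance_cm > 0 and math.isfinite(distance_cm)):
        raise ValueError("viewing distance must be positive")
    if extent_cm < 0 or not math.isfinite(extent_cm):
        raise ValueError("extent must be nonnegative and finite")
    return math.degrees(math.atan2(extent_cm, distance_cm))


def degrees_to_cm(angle_deg: float, distance_cm: float) -> float:
    """Inverse of :func:`cm_to_degrees` for angles below 90 degrees."""
    if not (distance_cm > 0 and math.isfinite(distance_cm)):
        raise ValueError("viewing distance must be positive")
    return math.tan(math.radians(angle_deg)) * distance_cm


def snap_to_screen(p, g: ScreenGeometry) -> np.ndarray:
    """Clamp point(s) componentwise onto the valid screen rectangle.

    Off-screen gaze estimates are snapped to the nearest valid screen
    location; on-screen points pass through unchanged.  Idempotent.
    """
    arr = _as_point(p)
    out = np.array(arr, dtype=float, copy=True)
    out[..., 0] = np.clip(out[..., 0], 0.0, g.width_px)
    out[..., 1] = np.clip(out[..., 1], 0.0, g.height_px)
    return out
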