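"""Fixation maps, saliency heatmaps, gaze entropy and heatmap comparison.

A fixation map counts fixations rounded to the nearest pixel; a saliency
heatmap is its Gaussian-blurred version (blur width 24 px by default, 67
px for one degree of mobile viewing angle).  Heatmaps are compared with
Pearson correlation at the pixel level and at the object level (mean
saliency per labelled object mask), against two baselines: heatmaps of
randomly shuffled stimuli, and a centred Gaussian (centre bias).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .events import OculomotorEvent

__all__ = [
    "SaliencyMap",
    "ObjectMaskSet",
    "fixation_map",
    "blur",
    "gaze_entropy",
    "pixel_correlation",
    "object_correlation",
    "shuffled_baseline",
    "center_bias_map",
]


@dataclass(frozen=True)
class SaliencyMap:
    """Nonnegative grid over stimulus pixels.

    ``blur_px`` records the Gaussian sigma applied (0 = raw fixation
    counts); ``n_fixations`` the number of fixations folded in.
    """

    grid: np.ndarray  # H x W, >= 0
    blur_px: float = 0.0
    n_fixations: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 2 or grid.size == 0:
            raise ValueError("grid must be a nonempty 2-D array")
        if np.any(grid < 0) or not np.all(np.isfinite(grid)):
            raise ValueError("grid values must be finite and nonnegative")
        object.__setattr__(self, "grid", grid)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.grid.shape

    @property
    def total(self) -> float:
        return float(self.grid.sum())

    @property
    def is_empty(self) -> bool:
        return self.total == 0.0

    def normalized(self) -> np.ndarray:
        """Probability map summing to 1 (requires positive total mass)."""
        tot = self.total
        if tot <= 0:
            raise ValueError("cannot normalize a zero-mass map")
        return self.grid / tot


@dataclass(frozen=True)
class ObjectMaskSet:
    """Labelled binary masks matching a heatmap's grid."""

    masks: Tuple[np.ndarray, ...]
    labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.masks) != len(self.labels):
            raise ValueError("one label per mask required")
        for m in self.masks:
            if m.ndim != 2 or not np.any(m):
                raise ValueError("masks must be nonempty 2-D arrays")
        shapes = {m.shape for m in self.masks}
        if len(shapes) != 1:
            raise ValueError("all masks must share one shape")


def _points_from(fixations) -> np.ndarray:
    pts = []
    for f in fixations:
        if isinstance(f, OculomotorEvent):
            pts.append(f.centroid)
        else:
            pts.append(tuple(f))
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def fixation_map(fixations: Sequence, shape: Tuple[int, int]) -> SaliencyMap:
    """Integer fixation-count map over an (H, W) grid.

    Fixation locations (events or (x, y) pairs) are rounded to the nearest
    pixel; out-of-bounds fixations are dropped, so the grid total equals
    the number of in-bounds fixations.
    """
    H, W = shape
    if H <= 0 or W <= 0:
        raise ValueError("shape must be positive")
    grid = np.zeros((H, W))
    pts = _points_from(fixations)
    n_in = 0
    for x, y in pts:
        xi, yi = int(round(x)), int(round(y))
        if 0 <= xi < W and 0 <= yi < H:
            grid[yi, xi] += 1
            n_in += 1
    return SaliencyMap(grid=grid, blur_px=0.0, n_fixations=n_in)


def blur(smap: SaliencyMap, blur_px: float = 24.0) -> SaliencyMap:
    """Gaussian-blurred saliency map with sigma = ``blur_px``.

    The kernel is truncated at 4 sigma; mass leaving the grid is folded
    back by reflecting at the boundary, so blurring is a linear operator
    that conserves total mass exactly.
    """
    if blur_px <= 0:
        raise ValueError("blur_px must be positive")
    out = gaussian_filter(smap.grid, sigma=blur_px, mode="reflect", truncate=4.0)
    return SaliencyMap(grid=np.maximum(out, 0.0), blur_px=blur_px,
                       n_fixations=smap.n_fixations)


def gaze_entropy(smap: SaliencyMap) -> float:
    """Shannon entropy (bits) of the normalized map over its grid cells.

    Ranges from 0 (single cell) to log2(H*W) (uniform).  The absolute
    value is conditional on the grid resolution, so report the grid shape
    alongside.
    """
    p = smap.normalized().ravel()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _normalized_flat(smap: SaliencyMap) -> np.ndarray:
    return smap.normalized().ravel()


def pixel_correlation(a: SaliencyMap, b: SaliencyMap) -> float:
    """Pearson correlation between two heatmaps over all pixels."""
    if a.shape != b.shape:
        raise ValueError("maps must share dimensions")
    va, vb = _normalized_flat(a), _normalized_flat(b)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("undefined correlation: constant map")
    return float(np.corrcoef(va, vb)[0, 1])


def object_correlation(a: SaliencyMap, b: SaliencyMap, masks: ObjectMaskSet) -> float:
    """Pearson correlation between per-object mean saliency scores."""
    if len(masks.masks) < 3:
        raise ValueError("object-level correlation needs >= 3 masks")
    if masks.masks[0].shape != a.shape or a.shape != b.shape:
        raise ValueError("masks and maps must share dimensions")
    na, nb = a.normalized(), b.normalized()
    sa = np.array([na[m.astype(bool)].mean() for m in masks.masks])
    sb = np.array([nb[m.astype(bool)].mean() for m in masks.masks])
    if np.ptp(sa) == 0 or np.ptp(sb) == 0:
        raise ValueError("undefined correlation: constant object scores")
    return float(np.corrcoef(sa, sb)[0, 1])


def shuffled_baseline(maps: Sequence[SaliencyMap], seed: int = 0) -> Tuple[np.ndarray, float]:
    """Shuffled-stimulus baseline correlations.

    Each map is correlated against the map of a different, randomly
    selected stimulus; returns the per-map r values and their mean.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    rng = np.random.default_rng(seed)
    rs = []
    for i in range(len(maps)):
        j = int(rng.integers(len(maps) - 1))
        if j >= i:
            j += 1
        rs.append(pixel_correlation(maps[i], maps[j]))
    rs = np.array(rs)
    return rs, float(rs.mean())


def center_bias_map(shape: Tuple[int, int], sigma_px: float) -> SaliencyMap:
    """Isotropic Gaussian centred on the grid, normalized to unit mass."""
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    H, W = shape
    y = np.arange(H) - (H - 1) / 2.0
    x = np.arange(W) - (W - 1) / 2.0
    gy = np.exp(-0.5 * (y / sigma_px) ** 2)
    gx = np.exp(-0.5 * (x / sigma_px) ** 2)
    grid = np.outer(gy, gx)
    grid /= grid.sum()
    return SaliencyMap(grid=grid, blur_px=sigma_px, n_fixations=0)
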