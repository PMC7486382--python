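"""Calibration-driven personalization of the base gaze network.

Personalization has two stages.  First the pre-trained base network is
fine-tuned on calibration data (all layers trainable, early-stopped on a
held-out calibration split).  Second, a lightweight per-user regression
head — one epsilon-insensitive support-vector regressor per screen
coordinate, RBF kernel — is fitted to the 4-D penultimate ReLU features of
the fine-tuned network against the known marker positions.  At inference
the network and the head run in sequence.

Accuracy is reported as the Euclidean error in screen cm between each
calibration marker and the median-aggregated personalized estimate for
that marker; participants whose mean hold-out error exceeds 1 cm are
excluded from downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from sklearn.svm import SVR

from .geometry import ErrorReport, GazeSample, ScreenGeometry, Stage, snap_to_screen
from .network import (EyeFrame, GazeNetwork, TrainOptions, extract_eye_crops,
                      train_base, evaluate_arrays)

__all__ = [
    "CalibrationRecord",
    "PersonalizedModel",
    "fine_tune",
    "fit_head",
    "evaluate",
    "exclusion_filter",
    "subsample_calibration",
    "interleaved_split",
]

#: Mean hold-out error (cm) above which a participant is discarded.
EXCLUSION_THRESHOLD_CM = 1.0


@dataclass(frozen=True)
class CalibrationRecord:
    """One calibration frame: camera frame + ground-truth marker position."""

    frame: EyeFrame
    marker: np.ndarray  # (2,) screen px
    session_id: str = "s0"

    def __post_init__(self) -> None:
        m = np.asarray(self.marker, dtype=float)
        if m.shape != (2,) or not np.all(np.isfinite(m)):
            raise ValueError("marker must be a finite 2-vector")
        object.__setattr__(self, "marker", m)


_crop_store: Dict[tuple, tuple] = {}


def _frame_arrays(frames: Sequence[EyeFrame], crop_scale: float):
    """Extract (and memoise) crops + normalised landmarks for frames."""
    L, R, LM = [], [], []
    for f in frames:
        key = (id(f), crop_scale)
        hit = _crop_store.get(key)
        if hit is None:
            crops = extract_eye_crops(f, crop_scale)
            hit = (crops.left, crops.right, f.normalized_landmarks)
            if len(_crop_store) > 4096:
                _crop_store.clear()
            _crop_store[key] = hit
        L.append(hit[0]); R.append(hit[1]); LM.append(hit[2])
    return np.stack(L), np.stack(R), np.stack(LM).astype(np.float32)


def compute_features(net: GazeNetwork, frames: Sequence[EyeFrame],
                     batch: int = 64) -> Tuple[np.ndarray, np.ndarray]:
    """Raw network estimates (cm) and penultimate features for frames."""
    L, R, LM = _frame_arrays(frames, net.crop_scale)
    ests, feats = [], []
    for i in range(0, len(L), batch):
        e, p = net.forward_batch(L[i:i + batch], R[i:i + batch], LM[i:i + batch])
        ests.append(e); feats.append(p)
    return np.concatenate(ests), np.concatenate(feats)


def _marker_key(marker: np.ndarray) -> tuple:
    return (round(float(marker[0]), 3), round(float(marker[1]), 3))


def interleaved_split(records: Sequence[CalibrationRecord],
                      holdout_every: int = 5) -> Tuple[list, list]:
    """Train/hold-out split that interleaves frames within each marker, so
    both halves cover the same screen locations."""
    by_marker: Dict[tuple, list] = {}
    for r in records:
        by_marker.setdefault(_marker_key(r.marker), []).append(r)
    train, hold = [], []
    for recs in by_marker.values():
        for i, r in enumerate(recs):
            (hold if i % holdout_every == holdout_every - 1 else train).append(r)
    if not hold and train:  # tiny sessions: reuse a training frame
        hold = [train[-1]]
    return train, hold


def subsample_calibration(records: Sequence[CalibrationRecord], n_frames: int,
                          seed: int = 0) -> List[CalibrationRecord]:
    """Pick ``n_frames`` spread uniformly across distinct marker locations."""
    if n_frames >= len(records):
        return list(records)
    by_marker: Dict[tuple, list] = {}
    for r in records:
        by_marker.setdefault(_marker_key(r.marker), []).append(r)
    rng = np.random.default_rng(seed)
    groups = [list(v) for v in by_marker.values()]
    for grp in groups:
        rng.shuffle(grp)
    rng.shuffle(groups)
    out: List[CalibrationRecord] = []
    gi = 0
    while len(out) < n_frames:
        grp = groups[gi % len(groups)]
        if grp:
            out.append(grp.pop())
        gi += 1
        if all(not grp for grp in groups):
            break
    return out


def fine_tune(base: GazeNetwork, records: Sequence[CalibrationRecord],
              g: ScreenGeometry, opts: Optional[TrainOptions] = None) -> GazeNetwork:
    """Fine-tune a copy of ``base`` on calibration records.

    All layer weights are trainable.  Convergence is operationalised as
    early stopping: training stops once the held-out calibration error has
    failed to improve for ``opts.patience`` evaluations, and the
    best-scoring weights are kept.  ``opts.steps == 0`` returns an
    unchanged copy.
    """
    if len(records) == 0:
        raise ValueError("cannot fine-tune on empty records")
    if opts is None:
        opts = TrainOptions(steps=300, batch_size=16, lr=3e-4, patience=10,
                            warmup_steps=0, revive_every=0)
    net = base.copy()
    if opts.steps == 0:
        return net
    train, hold = interleaved_split(records)
    dataset = [(r.frame, r.marker) for r in train]
    heldout = [(r.frame, r.marker) for r in hold]
    train_base(net, dataset, g, opts, heldout=heldout)
    return net


def _median_gamma(X: np.ndarray) -> float:
    """Median-heuristic RBF scale: gamma = 1 / median squared distance."""
    n = len(X)
    idx = np.arange(n) if n <= 400 else np.random.default_rng(0).choice(n, 400, replace=False)
    sub = X[idx]
    d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1)
    med = np.median(d2[d2 > 0]) if np.any(d2 > 0) else 1.0
    return 1.0 / float(med)


class PersonalizedModel:
    """Fine-tuned network + per-coordinate SVR heads.

    Build with :meth:`fit`; the heads are always fitted on features from
    the same network used at prediction time.
    """

    def __init__(self, base: GazeNetwork, head_x: SVR, head_y: SVR,
                 g: ScreenGeometry, n_calibration_frames: int):
        self.base = base
        self.head_x = head_x
        self.head_y = head_y
        self.geometry = g
        self.n_calibration_frames = n_calibration_frames

    @classmethod
    def fit(cls, net: GazeNetwork, records: Sequence[CalibrationRecord],
            g: ScreenGeometry, C: float = 20.0, epsilon: float = 0.01) -> "PersonalizedModel":
        """Fit the SVR heads on penultimate features of ``net``.

        ``epsilon`` is the insensitivity band in cm.  Requires records
        covering at least two distinct marker locations.
        """
        markers = {_marker_key(r.marker) for r in records}
        if len(markers) < 2:
            raise ValueError("insufficient calibration coverage: "
                             "need >= 2 distinct marker locations")
        frames = [r.frame for r in records]
        _, feats = compute_features(net, frames)
        targets_cm = np.stack([r.marker for r in records]) / g.px_per_cm
        gamma = _median_gamma(feats)
        head_x = SVR(kernel="rbf", C=C, epsilon=epsilon, gamma=gamma).fit(feats, targets_cm[:, 0])
        head_y = SVR(kernel="rbf", C=C, epsilon=epsilon, gamma=gamma).fit(feats, targets_cm[:, 1])
        return cls(net, head_x, head_y, g, len(records))

    def predict_many(self, frames: Sequence[EyeFrame]) -> np.ndarray:
        """Personalized gaze estimates in screen px, one row per frame.

        No snapping is applied: estimates may lie off-screen.
        """
        _, feats = compute_features(self.base, frames)
        est_cm = np.stack([self.head_x.predict(feats), self.head_y.predict(feats)], axis=1)
        return est_cm * self.geometry.px_per_cm

    def predict(self, frame: EyeFrame) -> GazeSample:
        xy = self.predict_many([frame])[0]
        return GazeSample(frame.t, float(xy[0]), float(xy[1]), Stage.PERSONALIZED)


def fit_head(net: GazeNetwork, records: Sequence[CalibrationRecord],
             g: ScreenGeometry, **kw) -> PersonalizedModel:
    """Functional alias for :meth:`PersonalizedModel.fit`."""
    return PersonalizedModel.fit(net, records, g, **kw)


def _predict_px(predictor, frames: Sequence[EyeFrame], g: ScreenGeometry) -> np.ndarray:
    if hasattr(predictor, "predict_many"):  # PersonalizedModel or any duck
        return predictor.predict_many(frames)
    est_cm, _ = compute_features(predictor, frames)  # bare GazeNetwork
    return est_cm * g.px_per_cm


def evaluate(predictor, heldout: Sequence[CalibrationRecord],
             g: ScreenGeometry) -> ErrorReport:
    """Per-marker calibration error of a model on held-out records.

    Estimates are snapped onto the screen, median-aggregated per distinct
    marker location, and compared with the marker in cm.  ``predictor``
    may be a :class:`PersonalizedModel` or a bare :class:`GazeNetwork`.
    """
    if len(heldout) == 0:
        raise ValueError("empty hold-out set")
    est_px = _predict_px(predictor, [r.frame for r in heldout], g)
    est_px = snap_to_screen(est_px, g)
    by_marker: Dict[tuple, list] = {}
    markers: Dict[tuple, np.ndarray] = {}
    for e, r in zip(est_px, heldout):
        key = _marker_key(r.marker)
        by_marker.setdefault(key, []).append(e)
        markers[key] = r.marker
    errors = []
    for key, ests in by_marker.items():
        med = np.median(np.stack(ests), axis=0)
        errors.append(float(np.linalg.norm(med - markers[key])) / g.px_per_cm)
    return ErrorReport.from_errors(errors)


def exclusion_filter(reports: Mapping[str, ErrorReport],
                     threshold_cm: float = EXCLUSION_THRESHOLD_CM) -> Set[str]:
    """Participants retained for analysis: mean hold-out error <= 1 cm.

    The rule is a strict ``>`` for exclusion, so exactly 1 cm is kept.
    """
    return {pid for pid, rep in reports.items() if rep.mean_error_cm <= threshold_cm}
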