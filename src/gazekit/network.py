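"""Base gaze-estimation network.

An appearance-based gaze estimator for front-camera phone frames: the two
eye regions are cropped around the eye-corner landmarks, scaled to
128 x 128 x 3, and passed through two *shared-weight* convolutional towers
(kernels 7x7, 5x5, 3x3 with 32, 64, 128 channels; strides 2, 2, 1; each
followed by 2x2 average pooling).  The left crop is mirrored horizontally
so one set of tower weights serves both eyes.  The four eye-corner
landmarks, normalised by the frame size, pass through three dense layers
(128, 16, 16 units); the concatenated tower outputs and landmark features
pass through two further dense layers (8, 4 units) and a linear head that
regresses the on-screen gaze point.  All hidden layers are ReLU.

Spatial trace through a tower: 128 -> 64 (conv s2) -> 32 (pool) -> 16
(conv s2) -> 8 (pool) -> 8 (conv s1) -> 4 (pool), i.e. 4*4*128 = 2048
features per eye.  With the default configuration the network has 166,294
trainable parameters (~170 K).

Gaze targets and estimates are expressed in screen centimetres (top-left
origin) so that evaluation errors are directly in cm; conversion to pixels
goes through :class:`~gazekit.geometry.ScreenGeometry`.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize

from . import nn
from .geometry import ScreenGeometry

__all__ = [
    "EyeFrame",
    "EyeCrops",
    "NetworkConfig",
    "GazeFeatures",
    "GazeNetwork",
    "TrainOptions",
    "extract_eye_crops",
    "parameter_count",
    "train_base",
]

CROP_SIZE = 128


@dataclass(frozen=True)
class EyeFrame:
    """A camera frame with its four eye-corner landmarks.

    ``landmarks`` is a (4, 2) array in frame pixel coordinates ordered
    [left-outer, left-inner, right-inner, right-outer], where "left" is the
    eye with smaller x in the image.  Face detection itself is out of
    scope: landmarks are an input.
    """

    image: np.ndarray  # H x W x 3, float in [0, 1]
    landmarks: np.ndarray  # 4 x 2 frame px
    t: float = 0.0

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=np.float32)
        lm = np.asarray(self.landmarks, dtype=np.float64)
        if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] == 0 or img.shape[1] == 0:
            raise ValueError("image must be a nonempty H x W x 3 array")
        if lm.shape != (4, 2):
            raise ValueError("landmarks must be a 4 x 2 array")
        H, W = img.shape[:2]
        if np.any(lm[:, 0] < 0) or np.any(lm[:, 0] > W) or np.any(lm[:, 1] < 0) or np.any(lm[:, 1] > H):
            raise ValueError("landmarks must lie inside the frame")
        object.__setattr__(self, "image", img)
        object.__setattr__(self, "landmarks", lm)

    @property
    def normalized_landmarks(self) -> np.ndarray:
        """Landmarks scaled to [0, 1] by the frame dimensions."""
        H, W = self.image.shape[:2]
        return self.landmarks / np.array([W, H], dtype=np.float64)


@dataclass(frozen=True)
class EyeCrops:
    """The two 128 x 128 x 3 eye crops; the left one is stored mirrored."""

    left: np.ndarray
    right: np.ndarray
    left_flipped: bool = True

    def __post_init__(self) -> None:
        for side in (self.left, self.right):
            if side.shape != (CROP_SIZE, CROP_SIZE, 3):
                raise ValueError(f"eye crops must be {CROP_SIZE}x{CROP_SIZE}x3")


@dataclass(frozen=True)
class NetworkConfig:
    conv_kernels: Tuple[int, int, int] = (7, 5, 3)
    conv_channels: Tuple[int, int, int] = (32, 64, 128)
    conv_strides: Tuple[int, int, int] = (2, 2, 1)
    pool_size: int = 2
    fc_units: Tuple[int, int, int, int, int] = (128, 16, 16, 8, 4)
    head_outputs: int = 2
    crop_size: int = CROP_SIZE

    def __post_init__(self) -> None:
        if len(self.fc_units) != 5:
            raise ValueError("fc_units must have length 5")
        if not (len(self.conv_kernels) == len(self.conv_channels) == len(self.conv_strides)):
            raise ValueError("conv specs must have equal length")
        if self.head_outputs < 1 or self.pool_size < 1:
            raise ValueError("invalid head/pool configuration")

    @property
    def tower_out_features(self) -> int:
        size = self.crop_size
        for s in self.conv_strides:
            size = -(-size // s)  # same padding conv
            size //= self.pool_size
        return size * size * self.conv_channels[-1]


@dataclass(frozen=True)
class GazeFeatures:
    """Network output: 2-D gaze estimate plus the 4-D penultimate ReLU
    activations that the personalization head consumes."""

    estimate: np.ndarray  # (2,) screen cm
    penultimate: np.ndarray  # (4,), nonnegative


def extract_eye_crops(frame: EyeFrame, crop_scale: float = 1.5) -> EyeCrops:
    """Crop both eye regions around the corner landmarks.

    Each crop is a square centred on the midpoint of the eye's two corner
    landmarks with side ``crop_scale`` times the inter-corner distance,
    zero-padded where it extends past the frame, resized to 128 x 128.
    The left crop is flipped horizontally so the shared-weight towers see
    both eyes in the same chirality.
    """
    lm = frame.landmarks
    crops = []
    for corners in (lm[0:2], lm[2:4]):
        d = float(np.linalg.norm(corners[1] - corners[0]))
        if d <= 0:
            raise ValueError("degenerate landmarks: zero inter-corner distance")
        center = corners.mean(axis=0)
        half = crop_scale * d / 2.0
        crops.append(_crop_square(frame.image, center, half))
    left = crops[0][:, ::-1, :].copy()  # mirror
    return EyeCrops(left=left, right=crops[1], left_flipped=True)


def _crop_square(img: np.ndarray, center: np.ndarray, half: float) -> np.ndarray:
    H, W = img.shape[:2]
    x0, x1 = int(round(center[0] - half)), int(round(center[0] + half))
    y0, y1 = int(round(center[1] - half)), int(round(center[1] + half))
    side = max(x1 - x0, y1 - y0, 1)
    out = np.zeros((side, side, 3), dtype=np.float32)
    sx0, sy0 = max(x0, 0), max(y0, 0)
    sx1, sy1 = min(x0 + side, W), min(y0 + side, H)
    if sx1 > sx0 and sy1 > sy0:
        out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = img[sy0:sy1, sx0:sx1]
    if side == CROP_SIZE:
        return out
    return resize(out, (CROP_SIZE, CROP_SIZE, 3), order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True).astype(np.float32)


def parameter_count(cfg: NetworkConfig = NetworkConfig()) -> int:
    """Closed-form trainable parameter count for a configuration.

    The towers share weights, so they are counted once.
    """
    n = 0
    in_ch = 3
    for k, c in zip(cfg.conv_kernels, cfg.conv_channels):
        n += k * k * in_ch * c + c
        in_ch = c
    lm_units = cfg.fc_units[:3]
    prev = 8
    for u in lm_units:
        n += prev * u + u
        prev = u
    comb_in = 2 * cfg.tower_out_features + lm_units[-1]
    prev = comb_in
    for u in cfg.fc_units[3:]:
        n += prev * u + u
        prev = u
    n += prev * cfg.head_outputs + cfg.head_outputs
    return n


class GazeNetwork:
    """The two-tower gaze regressor with explicit forward/backward passes."""

    def __init__(self, cfg: NetworkConfig = NetworkConfig(), seed: int = 0,
                 crop_scale: float = 1.5):
        self.cfg = cfg
        self.crop_scale = crop_scale
        rng = np.random.default_rng(seed)
        layers: List[nn.Layer] = []
        in_ch = 3
        for li, (k, c, s) in enumerate(zip(cfg.conv_kernels, cfg.conv_channels, cfg.conv_strides)):
            layers += [nn.Conv2d(in_ch, c, k, s, rng, compute_input_grad=li > 0),
                       nn.ReLU(), nn.AvgPool2d(cfg.pool_size)]
            in_ch = c
        layers.append(nn.Flatten())
        self.tower = nn.Sequential(layers)

        lm_layers: List[nn.Layer] = []
        prev = 8
        for u in cfg.fc_units[:3]:
            lm_layers += [nn.Dense(prev, u, rng), nn.ReLU()]
            prev = u
        self.landmark_path = nn.Sequential(lm_layers)

        comb_in = 2 * cfg.tower_out_features + cfg.fc_units[2]
        comb_layers: List[nn.Layer] = []
        prev = comb_in
        for u in cfg.fc_units[3:]:
            comb_layers += [nn.Dense(prev, u, rng), nn.ReLU()]
            prev = u
        self.combine_path = nn.Sequential(comb_layers)
        self.head = nn.Dense(prev, cfg.head_outputs, rng)
        # constant added to the linear head's output (cm); set to the mean
        # training target so the untrained net predicts the screen centre
        self.output_offset_cm = np.zeros(cfg.head_outputs, dtype=np.float64)

    # -- parameter plumbing -------------------------------------------
    def params(self) -> List[np.ndarray]:
        return (self.tower.params() + self.landmark_path.params()
                + self.combine_path.params() + self.head.params())

    def grads(self) -> List[np.ndarray]:
        return (self.tower.grads() + self.landmark_path.grads()
                + self.combine_path.grads() + self.head.grads())

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def copy(self) -> "GazeNetwork":
        clone = GazeNetwork(self.cfg, seed=0, crop_scale=self.crop_scale)
        for dst, src in zip(clone.params(), self.params()):
            dst[...] = src
        clone.output_offset_cm = self.output_offset_cm.copy()
        return clone

    # -- forward -------------------------------------------------------
    def forward_batch(self, left: np.ndarray, right: np.ndarray,
                      landmarks: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Batched forward pass.

        Parameters are (B,128,128,3) crops (left already mirrored) and
        (B,4,2) landmarks normalised to [0,1].  Returns ``(estimates,
        penultimate)`` with shapes (B,2) cm and (B,4).
        """
        if left.shape[1:] != (CROP_SIZE, CROP_SIZE, 3) or right.shape != left.shape:
            raise ValueError("crops must be B x 128 x 128 x 3")
        B = left.shape[0]
        stacked = np.concatenate([left, right], axis=0).astype(np.float32) - 0.5
        feats = self.tower.forward(stacked)
        fL, fR = feats[:B], feats[B:]
        lm_feats = self.landmark_path.forward(
            np.asarray(landmarks, dtype=np.float32).reshape(B, 8))
        comb_in = np.concatenate([fL, fR, lm_feats], axis=1)
        penult = self.combine_path.forward(comb_in)
        est = self.head.forward(penult)
        self._cache_B = B
        self._cache_comb_split = (fL.shape[1], fR.shape[1])
        return est.astype(np.float64) + self.output_offset_cm, penult.astype(np.float64)

    def backward_batch(self, g_est: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the estimates through the net."""
        B = self._cache_B
        nL, nR = self._cache_comb_split
        g = self.head.backward(g_est.astype(np.float32))
        g = self.combine_path.backward(g)
        gL, gR, gLm = g[:, :nL], g[:, nL : nL + nR], g[:, nL + nR :]
        self.landmark_path.backward(np.ascontiguousarray(gLm))
        self.tower.backward(np.concatenate([gL, gR], axis=0))

    def forward_frame(self, frame: EyeFrame) -> GazeFeatures:
        """Single-frame convenience wrapper returning :class:`GazeFeatures`."""
        crops = extract_eye_crops(frame, self.crop_scale)
        est, penult = self.forward_batch(
            crops.left[None], crops.right[None], frame.normalized_landmarks[None])
        return GazeFeatures(estimate=est[0], penultimate=penult[0])

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        meta = {"cfg": asdict(self.cfg), "crop_scale": self.crop_scale,
                "output_offset_cm": self.output_offset_cm.tolist()}
        arrays = {f"p{i}": p for i, p in enumerate(self.params())}
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "GazeNetwork":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            cfg_d = meta["cfg"]
            for key in ("conv_kernels", "conv_channels", "conv_strides", "fc_units"):
                cfg_d[key] = tuple(cfg_d[key])
            net = cls(NetworkConfig(**cfg_d), seed=0, crop_scale=meta["crop_scale"])
            net.output_offset_cm = np.asarray(meta.get("output_offset_cm",
                                                       [0.0, 0.0]), dtype=np.float64)
            for i, p in enumerate(net.params()):
                p[...] = data[f"p{i}"]
        return net


@dataclass
class TrainOptions:
    """Optimisation settings for base training and fine-tuning."""

    steps: int = 400
    batch_size: int = 16
    lr: float = 1e-3
    seed: int = 0
    eval_every: int = 25
    patience: Optional[int] = None  # early stop after N non-improving evals
    warmup_steps: int = 100  # linear lr ramp; protects narrow ReLU layers
    revive_every: int = 50  # reinitialise dead dense units (0 = off)


def _prepare_arrays(dataset: Sequence[Tuple[EyeFrame, np.ndarray]],
                    g: ScreenGeometry, crop_scale: float):
    """Extract crops/landmarks once; targets converted from px to cm."""
    L, R, LM, T = [], [], [], []
    for frame, target_px in dataset:
        crops = extract_eye_crops(frame, crop_scale)
        L.append(crops.left)
        R.append(crops.right)
        LM.append(frame.normalized_landmarks)
        T.append(np.asarray(target_px, dtype=np.float64) / g.px_per_cm)
    return (np.stack(L), np.stack(R), np.stack(LM).astype(np.float32),
            np.stack(T))


def _revive_dead_units(net: GazeNetwork, opt: nn.Adam,
                       L: np.ndarray, R: np.ndarray, LM: np.ndarray,
                       rng: np.random.Generator, probe: int = 64) -> int:
    """Reinitialise dense units that are inactive on a probe batch.

    The narrow dense funnel (8 then 4 units) can lose units to the dying
    ReLU problem early in training, which caps the network's capacity at
    one or two active pathways.  Dead units get fresh incoming weights, a
    small positive bias, and cleared optimizer state.  Returns the number
    of units revived.
    """
    n = min(probe, len(L))
    net.forward_batch(L[:n], R[:n], LM[:n])
    params = net.params()
    opt_index = {id(p): i for i, p in enumerate(params)}
    revived = 0
    for path in (net.landmark_path, net.combine_path):
        for dense, relu in zip(path.layers[::2], path.layers[1::2]):
            active = relu._mask.any(axis=0)
            for j in np.where(~active)[0]:
                fan_in = dense.W.shape[0]
                dense.W[:, j] = (rng.standard_normal(fan_in)
                                 * np.sqrt(2.0 / fan_in)).astype(np.float32)
                dense.b[j] = 0.1
                for arr, st_m, st_v in ((dense.W, opt.m[opt_index[id(dense.W)]],
                                         opt.v[opt_index[id(dense.W)]]),
                                        (dense.b, opt.m[opt_index[id(dense.b)]],
                                         opt.v[opt_index[id(dense.b)]])):
                    if arr.ndim == 2:
                        st_m[:, j] = 0.0
                        st_v[:, j] = 0.0
                    else:
                        st_m[j] = 0.0
                        st_v[j] = 0.0
                revived += 1
    return revived


def _euclidean_loss_grad(est: np.ndarray, targets: np.ndarray):
    """Mean Euclidean distance in cm and its gradient w.r.t. estimates."""
    d = est - targets
    dist = np.sqrt((d * d).sum(axis=1) + 1e-12)
    loss = float(dist.mean())
    grad = d / (dist[:, None] * len(d))
    return loss, grad


def train_base(net: GazeNetwork,
               dataset: Sequence[Tuple[EyeFrame, np.ndarray]],
               g: ScreenGeometry,
               opts: TrainOptions = TrainOptions(),
               heldout: Optional[Sequence[Tuple[EyeFrame, np.ndarray]]] = None,
               arrays: Optional[tuple] = None) -> dict:
    """Train ``net`` in place on (frame, target-px) pairs.

    Minimises the mean Euclidean error in screen cm with Adam.  Returns a
    history dict with ``loss`` per logged step and, when ``heldout`` is
    given, ``heldout_error_cm``; with ``patience`` set, training stops once
    the held-out error has failed to improve that many evaluations in a
    row, and the best-scoring weights are restored.
    """
    if arrays is None:
        if len(dataset) == 0:
            raise ValueError("empty training dataset")
        arrays = _prepare_arrays(dataset, g, net.crop_scale)
    L, R, LM, T = arrays
    n = len(L)
    if n == 0:
        raise ValueError("empty training dataset")
    held_arrays = None
    if heldout is not None:
        held_arrays = _prepare_arrays(heldout, g, net.crop_scale)

    if not np.any(net.output_offset_cm):
        net.output_offset_cm = T.mean(axis=0)

    rng = np.random.default_rng(opts.seed)
    opt = nn.Adam(net.params(), lr=opts.lr)
    history = {"step": [], "loss": [], "heldout_error_cm": []}
    best_err, best_params, bad_evals = np.inf, None, 0

    for step in range(opts.steps):
        # linear warmup then step decay: fast early progress without the
        # violent first updates that kill narrow ReLU layers
        frac = step / max(opts.steps, 1)
        warm = min(1.0, (step + 1) / opts.warmup_steps) if opts.warmup_steps else 1.0
        opt.lr = opts.lr * warm * (1.0 if frac < 0.5 else 0.3 if frac < 0.8 else 0.1)
        idx = rng.integers(0, n, size=min(opts.batch_size, n))
        est, _ = net.forward_batch(L[idx], R[idx], LM[idx])
        loss, grad = _euclidean_loss_grad(est, T[idx])
        net.backward_batch(grad)
        opt.step(net.grads())

        if (opts.revive_every and step > 0 and step < 0.8 * opts.steps
                and step % opts.revive_every == 0):
            _revive_dead_units(net, opt, L, R, LM, rng)

        if step % opts.eval_every == 0 or step == opts.steps - 1:
            history["step"].append(step)
            history["loss"].append(loss)
            if held_arrays is not None:
                err = evaluate_arrays(net, held_arrays)
                history["heldout_error_cm"].append(err)
                if err < best_err - 1e-6:
                    best_err, bad_evals = err, 0
                    best_params = [p.copy() for p in net.params()]
                else:
                    bad_evals += 1
                    if opts.patience is not None and bad_evals >= opts.patience:
                        break
    if best_params is not None:
        for p, bp in zip(net.params(), best_params):
            p[...] = bp
    return history


def evaluate_arrays(net: GazeNetwork, arrays: tuple, batch: int = 64) -> float:
    """Mean Euclidean error (cm) of the raw network on prepared arrays."""
    L, R, LM, T = arrays
    errs = []
    for i in range(0, len(L), batch):
        est, _ = net.forward_batch(L[i : i + batch], R[i : i + batch], LM[i : i + batch])
        errs.append(np.linalg.norm(est - T[i : i + batch], axis=1))
    return float(np.concatenate(errs).mean())
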