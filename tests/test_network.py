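"""Gaze network architecture, crop extraction and training behaviour."""

import numpy as np
import pytest

from gazekit.geometry import ScreenGeometry
from gazekit.network import (CROP_SIZE, EyeFrame, GazeNetwork, NetworkConfig,
                             TrainOptions, extract_eye_crops, parameter_count,
                             train_base, evaluate_arrays, _prepare_arrays)
from gazekit.synth import SyntheticEyeParams, default_geometry, render_eye_frame


@pytest.fixture(scope="module")
def small_net():
    # a thin variant of the architecture for fast forward tests
    cfg = NetworkConfig(conv_channels=(4, 6, 8), fc_units=(16, 8, 8, 6, 4))
    return GazeNetwork(cfg, seed=0)


def _random_frame(rng, w=256, h=160):
    img = rng.random((h, w, 3)).astype(np.float32)
    lm = np.array([[40.0, 80.0], [104.0, 80.0], [152.0, 80.0], [216.0, 80.0]])
    return EyeFrame(image=img, landmarks=lm, t=0.0)


class TestParameterCount:
    def test_first_tower_layer_closed_form(self):
        # 7*7*3*32 weights + 32 biases
        net = GazeNetwork(NetworkConfig(), seed=0)
        first_conv = net.tower.layers[0]
        assert first_conv.n_params == 7 * 7 * 3 * 32 + 32 == 4736

    def test_default_total(self):
        assert parameter_count(NetworkConfig()) == 166294

    def test_closed_form_matches_built_network(self):
        for cfg in (NetworkConfig(),
                    NetworkConfig(conv_channels=(4, 6, 8), fc_units=(16, 8, 8, 6, 4))):
            assert parameter_count(cfg) == GazeNetwork(cfg, seed=0).n_params

    def test_tower_feature_width(self):
        # spatial trace 128 -> 64 -> 32 -> 16 -> 8 -> 8 -> 4; 4*4*128 features
        assert NetworkConfig().tower_out_features == 4 * 4 * 128


class TestEyeCrops:
    def test_output_shape_contract(self, rng):
        crops = extract_eye_crops(_random_frame(rng))
        assert crops.left.shape == (CROP_SIZE, CROP_SIZE, 3)
        assert crops.right.shape == (CROP_SIZE, CROP_SIZE, 3)
        assert crops.left_flipped

    def test_mirror_involution(self, rng):
        crops = extract_eye_crops(_random_frame(rng))
        twice = crops.left[:, ::-1, :][:, ::-1, :]
        assert np.array_equal(twice, crops.left)

    def test_landmarks_at_edge_still_128(self, rng):
        img = rng.random((160, 256, 3)).astype(np.float32)
        lm = np.array([[0.0, 5.0], [60.0, 5.0], [150.0, 5.0], [210.0, 5.0]])
        crops = extract_eye_crops(EyeFrame(image=img, landmarks=lm))
        assert crops.left.shape == (128, 128, 3)

    def test_degenerate_landmarks_rejected(self, rng):
        img = rng.random((160, 256, 3)).astype(np.float32)
        lm = np.array([[50.0, 80.0], [50.0, 80.0], [150.0, 80.0], [216.0, 80.0]])
        with pytest.raises(ValueError):
            extract_eye_crops(EyeFrame(image=img, landmarks=lm))

    def test_synthetic_iris_lands_at_predicted_crop_position(self):
        # the renderer displaces the iris by gain*(gaze-center); the crop is
        # centred on the eye, so the darkest crop pixel should sit at the
        # crop centre plus the scaled displacement (mirrored for the left eye)
        g = default_geometry()
        user = SyntheticEyeParams(noise_sd=0.0)
        gaze_cm = np.array([g.width_cm / 2 + 2.0, g.height_cm / 2 - 3.0])
        frame, truth = render_eye_frame(gaze_cm, user, g)
        disp = truth["iris_displacement_px"]
        crops = extract_eye_crops(frame)
        # crop side = 1.5 * 64 px inter-corner distance, resized to 128
        scale = 128.0 / 96.0

        def iris_centroid(crop):
            # iris (0.10) is darker than background (0.20) and sclera (0.95)
            w = np.maximum(0.15 - crop[:, :, 0], 0.0)
            ys, xs = np.mgrid[0:128, 0:128]
            return ((w * ys).sum() / w.sum(), (w * xs).sum() / w.sum())

        got_r = iris_centroid(crops.right)
        expect_r = (64 + disp[1] * scale, 64 + disp[0] * scale)
        assert abs(got_r[0] - expect_r[0]) <= 2 and abs(got_r[1] - expect_r[1]) <= 2
        got_l = iris_centroid(crops.left)
        expect_l = (64 + disp[1] * scale, 127 - (64 + disp[0] * scale))
        assert abs(got_l[0] - expect_l[0]) <= 2 and abs(got_l[1] - expect_l[1]) <= 2


class TestForward:
    def test_zero_weights_give_zero_output(self, small_net, rng):
        cfg = small_net.cfg
        net = GazeNetwork(cfg, seed=1)
        for p in net.params():
            p[...] = 0.0
        L = rng.random((2, 128, 128, 3), dtype=np.float32)
        R = rng.random((2, 128, 128, 3), dtype=np.float32)
        LM = rng.random((2, 4, 2)).astype(np.float32)
        est, penult = net.forward_batch(L, R, LM)
        assert np.allclose(est, 0.0)
        assert np.allclose(penult, 0.0)

    def test_deterministic_given_weights(self, small_net, rng):
        L = rng.random((1, 128, 128, 3), dtype=np.float32)
        R = rng.random((1, 128, 128, 3), dtype=np.float32)
        LM = rng.random((1, 4, 2)).astype(np.float32)
        a = small_net.forward_batch(L, R, LM)
        b = small_net.forward_batch(L, R, LM)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_penultimate_nonnegative(self, small_net, rng):
        for _ in range(20):
            L = rng.random((1, 128, 128, 3), dtype=np.float32)
            R = rng.random((1, 128, 128, 3), dtype=np.float32)
            LM = rng.random((1, 4, 2)).astype(np.float32)
            _, penult = small_net.forward_batch(L, R, LM)
            assert np.all(penult >= 0)

    def test_wrong_crop_shape_rejected(self, small_net, rng):
        bad = rng.random((1, 64, 64, 3), dtype=np.float32)
        with pytest.raises(ValueError):
            small_net.forward_batch(bad, bad, rng.random((1, 4, 2)))

    def test_shared_tower_symmetry(self, small_net, rng):
        # identical left/right crops with symmetric landmarks: both towers
        # share weights so each contributes the same features
        crop = rng.random((1, 128, 128, 3), dtype=np.float32)
        stacked = np.concatenate([crop, crop], axis=0).astype(np.float32) - 0.5
        feats = small_net.tower.forward(stacked)
        assert np.array_equal(feats[0], feats[1])


class TestTraining:
    def test_empty_dataset_rejected(self, geometry):
        net = GazeNetwork(NetworkConfig(conv_channels=(2, 2, 2),
                                        fc_units=(8, 4, 4, 4, 4)), seed=0)
        with pytest.raises(ValueError):
            train_base(net, [], geometry)

    def test_memorizes_single_example(self, geometry):
        g = geometry
        user = SyntheticEyeParams(noise_sd=0.0)
        frame, _ = render_eye_frame(np.array([2.0, 3.0]), user, g)
        target = np.array([2.0, 3.0]) * g.px_per_cm
        cfg = NetworkConfig(conv_channels=(2, 4, 4), fc_units=(8, 8, 8, 6, 4))
        net = GazeNetwork(cfg, seed=0)
        hist = train_base(net, [(frame, target)] * 4, g,
                          TrainOptions(steps=80, batch_size=4, lr=3e-3, seed=0))
        arrays = _prepare_arrays([(frame, target)], g, net.crop_scale)
        assert evaluate_arrays(net, arrays) < 0.2  # cm

    def test_loss_halves_on_small_synthetic_set(self, geometry):
        # 50 frames with distinct gaze targets, 200 steps: training loss
        # should drop by at least 50% from its starting value
        g = geometry
        r = np.random.default_rng(7)
        user = SyntheticEyeParams(noise_sd=0.01)
        data = []
        for _ in range(50):
            gaze = np.array([r.uniform(1, g.width_cm - 1), r.uniform(1, g.height_cm - 1)])
            frame, _ = render_eye_frame(gaze, user, g, rng=r)
            data.append((frame, gaze * g.px_per_cm))
        cfg = NetworkConfig(conv_channels=(4, 8, 8), fc_units=(16, 8, 8, 6, 4))
        net = GazeNetwork(cfg, seed=0)
        arrays = _prepare_arrays(data, g, net.crop_scale)
        start = evaluate_arrays(net, arrays)
        hist = train_base(net, data, g,
                          TrainOptions(steps=200, batch_size=16, lr=1e-3, seed=0),
                          arrays=arrays)
        end = evaluate_arrays(net, arrays)
        assert end < 0.5 * start

    def test_checkpoint_round_trip_bit_exact(self, tmp_path, rng, geometry):
        cfg = NetworkConfig(conv_channels=(2, 4, 4), fc_units=(8, 8, 8, 6, 4))
        net = GazeNetwork(cfg, seed=3)
        net.output_offset_cm = np.array([4.0, 8.0])
        path = tmp_path / "ckpt.npz"
        net.save(path)
        loaded = GazeNetwork.load(path)
        L = rng.random((1, 128, 128, 3), dtype=np.float32)
        R = rng.random((1, 128, 128, 3), dtype=np.float32)
        LM = rng.random((1, 4, 2)).astype(np.float32)
        a, fa = net.forward_batch(L, R, LM)
        b, fb = loaded.forward_batch(L, R, LM)
        assert np.array_equal(a, b) and np.array_equal(fa, fb)
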