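"""Task protocol generation and per-trial metrics."""

import math

import numpy as np
import pytest

from gazekit.events import OculomotorEvent
from gazekit.geometry import GazeSample, ScreenGeometry, degrees_to_cm
from gazekit.protocols import (DotCalibrationProtocol, ProsaccadeTrial,
                               fixations_to_target, generate_prosaccade_trial,
                               generate_pursuit_path, generate_search_display,
                               pursuit_tracking_error)


class TestPursuitPath:
    def test_circle_radius_from_eccentricity(self, geometry):
        # at 30 cm viewing distance a 7 degree circle has radius
        # 30*tan(7 deg) = 3.68 cm
        path = generate_pursuit_path("circle", geometry)
        r_px = np.linalg.norm(path.xy[0] - geometry.center_px)
        assert r_px / geometry.px_per_cm == pytest.approx(3.6835, abs=2e-3)

    def test_starts_and_ends_at_rightmost_point(self, geometry):
        path = generate_pursuit_path("circle", geometry)
        assert np.allclose(path.xy[0], path.xy[-1])
        assert path.xy[0][0] == pytest.approx(
            geometry.center_px[0] + 3.6835 * geometry.px_per_cm, rel=1e-3)
        assert path.xy[:, 0].max() <= path.xy[0][0] + 1e-6

    def test_clockwise_under_ydown(self, geometry):
        path = generate_pursuit_path("circle", geometry)
        x, y = path.xy[:-1, 0], path.xy[:-1, 1]
        x2, y2 = path.xy[1:, 0], path.xy[1:, 1]
        shoelace = np.sum(x * y2 - x2 * y) / 2.0
        # under y-down screen coordinates, visually clockwise motion has
        # positive shoelace area
        assert shoelace > 0

    def test_radius_exceeding_screen_rejected(self):
        tiny = ScreenGeometry(width_px=200, height_px=400, px_per_cm=100.0,
                              viewing_distance_cm=30.0)
        with pytest.raises(ValueError):
            generate_pursuit_path("circle", tiny)

    def test_zigzag_monotone_descent(self, geometry):
        path = generate_pursuit_path("zigzag", geometry, period_s=60.0)
        assert np.all(np.diff(path.xy[:, 1]) >= 0)

    def test_box_closes_and_stays_on_square(self, geometry):
        path = generate_pursuit_path("box", geometry)
        assert np.allclose(path.xy[0], path.xy[-1])
        r = 3.6835 * geometry.px_per_cm
        d = np.abs(path.xy - geometry.center_px)
        assert np.all(np.isclose(d.max(axis=1), r, atol=1.0))


class TestPursuitError:
    def test_perfect_tracking_zero_error(self, geometry):
        path = generate_pursuit_path("circle", geometry)
        trace = [GazeSample(float(t), float(p[0]), float(p[1]))
                 for t, p in zip(path.t, path.xy)]
        assert pursuit_tracking_error(trace, path, geometry) == pytest.approx(0.0)

    def test_constant_offset_half_cm(self, geometry):
        path = generate_pursuit_path("circle", geometry)
        off = 0.5 * geometry.px_per_cm
        trace = [GazeSample(float(t), float(p[0] + off), float(p[1]))
                 for t, p in zip(path.t, path.xy)]
        assert pursuit_tracking_error(trace, path, geometry) == pytest.approx(0.5)

    def test_lag_equals_chord_formula(self, geometry):
        # a pursuer trailing by lag L on a circle of radius r sits at a
        # constant chord distance 2 r sin(pi L / period)
        period, lag = 8.0, 0.12
        path = generate_pursuit_path("circle", geometry, period_s=period, n_cycles=2)
        ts = path.t[(path.t >= lag)]
        lagged = path.at(ts - lag)
        trace = [GazeSample(float(t), float(p[0]), float(p[1]))
                 for t, p in zip(ts, lagged)]
        err = pursuit_tracking_error(trace, path, geometry)
        r_cm = degrees_to_cm(7.0, geometry.viewing_distance_cm)
        want = 2 * r_cm * math.sin(math.pi * lag / period)
        assert err == pytest.approx(want, rel=0.02)

    def test_disjoint_time_ranges_rejected(self, geometry):
        path = generate_pursuit_path("circle", geometry)
        trace = [GazeSample(100.0, 0.0, 0.0)]
        with pytest.raises(ValueError):
            pursuit_tracking_error(trace, path, geometry)

    def test_invariant_to_rigid_translation(self, geometry):
        path = generate_pursuit_path("circle", geometry)
        rng = np.random.default_rng(0)
        gaze = path.xy + rng.normal(0, 30, path.xy.shape)
        t0 = [GazeSample(float(t), float(p[0]), float(p[1]))
              for t, p in zip(path.t, gaze)]
        e0 = pursuit_tracking_error(t0, path, geometry)
        shift = np.array([55.0, -40.0])
        from gazekit.protocols import PursuitPath
        path2 = PursuitPath(path.shape, path.t, path.xy + shift, path.period_s,
                            path.eccentricity_deg)
        t1 = [GazeSample(float(t), float(p[0] + shift[0]), float(p[1] + shift[1]))
              for t, p in zip(path.t, gaze)]
        assert pursuit_tracking_error(t1, path2, geometry) == pytest.approx(e0)


class TestSearchDisplay:
    def test_reproducible_given_seed(self, geometry):
        a = generate_search_display(10, "orientation", 15.0, 7, geometry)
        b = generate_search_display(10, "orientation", 15.0, 7, geometry)
        assert a == b

    def test_one_target_with_offset_orientation(self, geometry):
        d = generate_search_display(10, "orientation", 15.0, 7, geometry)
        assert d.set_size == 10
        assert len(d.distractors) == 9
        base = d.distractors[0].feature
        assert all(i.feature == base for i in d.distractors)
        assert d.target.feature == pytest.approx((base + 15.0) % 180.0)

    def test_zero_contrast_rejected(self, geometry):
        with pytest.raises(ValueError):
            generate_search_display(10, "orientation", 0.0, 7, geometry)

    def test_minimum_spacing_enforced(self, geometry):
        d = generate_search_display(15, "color_intensity", 0.3, 3, geometry)
        pos = np.array([i.position for i in d.items])
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                assert np.linalg.norm(pos[i] - pos[j]) >= 3.0 * d.item_radius_px

    def test_impossible_packing_rejected(self):
        small = ScreenGeometry(width_px=600, height_px=700, px_per_cm=100.0,
                               viewing_distance_cm=30.0)
        with pytest.raises(ValueError):
            generate_search_display(40, "orientation", 15.0, 1, small)


class TestFixationsToTarget:
    def _fix(self, t, pos, dur=0.2):
        return OculomotorEvent("fixation", t, t + dur, centroid=pos)

    def test_first_fixation_on_target(self, geometry):
        d = generate_search_display(5, "orientation", 15.0, 11, geometry)
        ev = [self._fix(0.0, d.target.position)]
        n, dur = fixations_to_target(ev, d)
        assert n == 1 and dur == pytest.approx(0.2)

    def test_two_distractors_then_target(self, geometry):
        d = generate_search_display(5, "orientation", 15.0, 11, geometry)
        dis = d.distractors
        ev = [self._fix(0.0, dis[0].position, 0.3),
              self._fix(0.4, dis[1].position, 0.25),
              self._fix(0.8, d.target.position, 0.2)]
        n, dur = fixations_to_target(ev, d)
        assert n == 3
        assert dur == pytest.approx(0.75)

    def test_never_on_target_is_missing(self, geometry):
        d = generate_search_display(5, "orientation", 15.0, 11, geometry)
        ev = [self._fix(0.0, d.distractors[0].position)]
        assert fixations_to_target(ev, d) == (None, None)


class TestProsaccadeTrial:
    def test_uniform_target_sampling_spans_screen(self, geometry, rng):
        targets = np.array([generate_prosaccade_trial(geometry, rng).target
                            for _ in range(300)])
        assert targets[:, 0].min() < 0.2 * geometry.width_px
        assert targets[:, 0].max() > 0.8 * geometry.width_px
        assert targets[:, 1].min() < 0.2 * geometry.height_px
        assert targets[:, 1].max() > 0.8 * geometry.height_px

    def test_defaults(self):
        t = ProsaccadeTrial(target=(100.0, 100.0))
        assert t.fixation_ms == 800.0
        assert t.target_duration_ms == 1000.0
        assert t.marker_pulse_px == (60.0, 168.0)
        assert t.n_pulses == 3

    def test_dot_protocol_pulse_bounds(self):
        p = DotCalibrationProtocol()
        assert p.pulse_dp == (18.0, 50.0)
        with pytest.raises(ValueError):
            DotCalibrationProtocol(pulse_dp=(50.0, 18.0))
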