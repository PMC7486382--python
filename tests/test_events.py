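"""Event detection against brute-force references and constructed traces."""

import math

import numpy as np
import pytest

from gazekit.events import (EventConfig, aggregate_per_stimulus,
                            arrays_to_trace, bilateral_smooth, classify_ivt,
                            extract_events, extract_fixations, saccade_latency,
                            trace_to_arrays)
from gazekit.geometry import GazeSample, cm_to_degrees, degrees_to_cm
from gazekit.synth import ScanpathParams, simulate_scanpath


def _make_trace(t, xy):
    return arrays_to_trace(np.asarray(t, dtype=float), np.asarray(xy, dtype=float))


def _bilateral_bruteforce(t, xy, cfg):
    """Double loop over all neighbours within +-3 temporal sigma."""
    sig_t = cfg.bilateral_time_ms / 1000.0
    sig_s = cfg.bilateral_space_px
    out = np.empty_like(xy)
    for i in range(len(t)):
        num = np.zeros(2)
        den = 0.0
        for j in range(len(t)):
            if abs(t[j] - t[i]) > 3 * sig_t:
                continue
            w = math.exp(-0.5 * ((t[j] - t[i]) / sig_t) ** 2
                         - 0.5 * (np.linalg.norm(xy[j] - xy[i]) / sig_s) ** 2)
            num += w * xy[j]
            den += w
        out[i] = num / den
    return out


def _ivt_bruteforce(t, xy, cfg, g):
    labels = np.zeros(len(t), dtype=bool)
    for i in range(len(t)):
        j0, j1 = max(i - 1, 0), min(i + 1, len(t) - 1)
        dt = t[j1] - t[j0]
        if dt <= 0:
            continue
        chord_cm = np.linalg.norm(xy[j1] - xy[j0]) / g.px_per_cm
        deg = math.degrees(math.atan2(chord_cm, g.viewing_distance_cm))
        labels[i] = deg / dt >= cfg.velocity_threshold_deg_s
    return labels


class TestBilateralSmooth:
    def test_constant_trace_is_fixed_point(self, event_config):
        t = np.arange(30) / 30.0
        xy = np.full((30, 2), 123.0)
        out = bilateral_smooth(_make_trace(t, xy), event_config)
        _, oxy = trace_to_arrays(out)
        assert np.allclose(oxy, xy)

    def test_matches_bruteforce_double_loop(self, event_config, rng):
        t = np.sort(rng.uniform(0, 3, 120))
        xy = rng.uniform(0, 1000, (120, 2))
        out = bilateral_smooth(_make_trace(t, xy), event_config)
        _, oxy = trace_to_arrays(out)
        want = _bilateral_bruteforce(t, xy, event_config)
        assert np.allclose(oxy, want, atol=1e-9)

    def test_preserves_steps_better_than_gaussian(self, event_config):
        # outlier spike within a fixation is attenuated; a genuine step
        # (large spatial separation) is preserved better than with the
        # spatially-blind Gaussian of the same temporal scale
        t = np.arange(60) / 30.0
        xy = np.zeros((60, 2))
        xy[30:] = (600.0, 0.0)     # step of 600 px (>> 200 px spatial scale)
        xy[10] = (80.0, 0.0)       # 80 px spike (within spatial scale)
        out = bilateral_smooth(_make_trace(t, xy), event_config)
        _, oxy = trace_to_arrays(out)
        assert abs(oxy[10, 0]) < 40.0  # spike pulled toward neighbours
        # plain temporal Gaussian for comparison
        sig_t = event_config.bilateral_time_ms / 1000.0
        w = np.exp(-0.5 * ((t[:, None] - t[None, :]) / sig_t) ** 2)
        gauss = (w / w.sum(1, keepdims=True)) @ xy
        i_edge = 29
        assert abs(oxy[i_edge, 0] - xy[i_edge, 0]) < abs(gauss[i_edge, 0] - xy[i_edge, 0])

    def test_unsorted_trace_rejected(self, event_config):
        trace = _make_trace([0.1, 0.0], [[0, 0], [1, 1]])
        with pytest.raises(ValueError):
            bilateral_smooth(trace, event_config)

    def test_length_and_timestamps_unchanged(self, event_config, rng):
        t = np.sort(rng.uniform(0, 2, 40))
        trace = _make_trace(t, rng.uniform(0, 500, (40, 2)))
        out = bilateral_smooth(trace, event_config)
        assert len(out) == 40
        assert np.allclose([s.t for s in out], t)


class TestClassifyIVT:
    def test_stationary_all_fixation(self, event_config, geometry):
        t = np.arange(30) / 30.0
        trace = _make_trace(t, np.full((30, 2), 500.0))
        assert not classify_ivt(trace, event_config, geometry).any()

    def test_matches_bruteforce_on_random_traces(self, event_config, geometry, rng):
        for _ in range(20):
            n = 200
            t = np.cumsum(rng.uniform(0.02, 0.05, n))
            xy = np.cumsum(rng.normal(0, 30, (n, 2)), axis=0) + 500
            trace = _make_trace(t, xy)
            got = classify_ivt(trace, event_config, geometry)
            want = _ivt_bruteforce(t, xy, event_config, geometry)
            assert np.array_equal(got, want)

    def test_exact_threshold_is_saccade(self, geometry):
        # velocity exactly equal to the threshold is classified saccade:
        # set the threshold to the bit-exact velocity of a constructed step
        g = geometry
        step_px = degrees_to_cm(22.0 / 30.0, g.viewing_distance_cm) * g.px_per_cm
        t = np.arange(10) / 30.0
        xy = np.stack([500 + step_px * np.arange(10), np.full(10, 500.0)], axis=1)
        # bit-exact chord of the one-sided difference at sample 0
        chord_cm = float(np.linalg.norm(xy[1] - xy[0])) / g.px_per_cm
        v_exact = cm_to_degrees(chord_cm, g.viewing_distance_cm) / (t[1] - t[0])
        cfg = EventConfig(velocity_threshold_deg_s=v_exact)
        labels = classify_ivt(_make_trace(t, xy), cfg, g)
        assert labels[0]
        # marginally slower threshold keeps it saccade; marginally faster
        # threshold flips the boundary sample to fixation
        assert classify_ivt(_make_trace(t, xy),
                            EventConfig(velocity_threshold_deg_s=v_exact * (1 + 1e-9)),
                            g)[0] == False  # noqa: E712

    def test_too_short_trace_rejected(self, event_config, geometry):
        with pytest.raises(ValueError):
            classify_ivt(_make_trace([0.0], [[0, 0]]), event_config, geometry)


class TestExtractFixations:
    def test_single_stationary_trace(self, event_config, geometry):
        t = np.arange(16) / 30.0  # 500 ms
        trace = _make_trace(t, np.full((16, 2), 300.0))
        labels = classify_ivt(trace, event_config, geometry)
        fixes = extract_fixations(labels, trace, event_config)
        assert len(fixes) == 1
        assert fixes[0].duration == pytest.approx(0.5)
        assert fixes[0].centroid == (300.0, 300.0)

    def test_short_run_dropped(self, event_config):
        # 80 ms fixation run between saccades: below the 100 ms minimum
        t = np.arange(10) * 0.02
        trace = _make_trace(t, np.zeros((10, 2)))
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 0, 1, 1], dtype=bool)
        # fixation run spans indices 3..7 -> 80 ms
        fixes = extract_fixations(labels, trace, event_config)
        assert fixes == []

    def test_events_non_overlapping_and_ordered(self, event_config, geometry, rng):
        params = ScanpathParams(seed=9)
        pts = [rng.uniform([100, 100], [1300, 2700]) for _ in range(8)]
        sim = simulate_scanpath({"kind": "fixations", "points": pts}, params,
                                geometry, rng=rng)
        sm = bilateral_smooth(sim.trace, event_config)
        labels = classify_ivt(sm, event_config, geometry)
        events = extract_events(labels, sm, event_config, geometry)
        for a, b in zip(events, events[1:]):
            assert a.onset < a.offset
            assert a.offset <= b.onset + 1e-9

    def test_no_sub_minimum_fixations_emitted(self, event_config, geometry, rng):
        params = ScanpathParams(seed=4)
        pts = [rng.uniform([100, 100], [1300, 2700]) for _ in range(10)]
        sim = simulate_scanpath({"kind": "fixations", "points": pts}, params,
                                geometry, rng=rng)
        sm = bilateral_smooth(sim.trace, event_config)
        labels = classify_ivt(sm, event_config, geometry)
        for e in extract_fixations(labels, sm, event_config):
            assert e.duration * 1000.0 >= event_config.min_fixation_ms


class TestSaccadeLatency:
    def test_programmed_latency_recovered(self, event_config, geometry):
        from gazekit.protocols import ProsaccadeTrial
        params = ScanpathParams(seed=1, noise_sd_px=5.0,
                                saccade_latency_mean_s=0.2,
                                saccade_latency_shape=1e6)  # ~deterministic 200 ms
        trial = ProsaccadeTrial(target=(1200.0, 2500.0))
        sim = simulate_scanpath(trial, params, geometry)
        lat = saccade_latency(sim.trace, trial.stimulus_onset_s, event_config, geometry)
        assert lat == pytest.approx(200.0, abs=34.0)  # one frame at 30 Hz

    def test_no_movement_gives_missing(self, event_config, geometry):
        t = np.arange(30) / 30.0
        trace = _make_trace(t, np.full((30, 2), 700.0))
        assert saccade_latency(trace, 0.2, event_config, geometry) is None

    def test_onset_outside_span_rejected(self, event_config, geometry):
        t = np.arange(30) / 30.0
        trace = _make_trace(t, np.full((30, 2), 700.0))
        with pytest.raises(ValueError):
            saccade_latency(trace, 5.0, event_config, geometry)


class TestAggregatePerStimulus:
    def test_discards_initial_800ms(self, event_config, geometry):
        # 1000 ms stimulus at 30 Hz: only samples in the last ~200 ms count
        t = np.arange(30) / 30.0
        xy = np.zeros((30, 2))
        xy[t >= 0.8] = 900.0  # post-discard samples have a distinct value
        out = aggregate_per_stimulus(_make_trace(t, xy), [(0.0, 1.0)],
                                     event_config, geometry)
        assert np.allclose(out[0], (900.0, 900.0))

    def test_odd_count_median(self, event_config, geometry):
        t = [0.81, 0.85, 0.9]
        xy = [[0, 0], [10, 10], [100, 100]]
        out = aggregate_per_stimulus(_make_trace(t, xy), [(0.0, 1.0)],
                                     event_config, geometry)
        assert np.allclose(out[0], (10.0, 10.0))

    def test_snap_happens_before_median(self, event_config, geometry):
        t = [0.81, 0.85, 0.9]
        xy = [[-20, 50], [-20, 50], [-20, 50]]
        out = aggregate_per_stimulus(_make_trace(t, xy), [(0.0, 1.0)],
                                     event_config, geometry)
        assert np.allclose(out[0], (0.0, 50.0))

    def test_fully_discarded_interval_is_missing(self, event_config, geometry):
        t = np.arange(15) / 30.0  # 500 ms of samples only
        out = aggregate_per_stimulus(_make_trace(t, np.zeros((15, 2))),
                                     [(0.0, 0.5)], event_config, geometry)
        assert out[0] is None

    def test_overlapping_intervals_rejected(self, event_config, geometry):
        t = np.arange(60) / 30.0
        trace = _make_trace(t, np.zeros((60, 2)))
        with pytest.raises(ValueError):
            aggregate_per_stimulus(trace, [(0.0, 1.0), (0.5, 1.5)],
                                   event_config, geometry)


class TestInvariances:
    def test_fixation_count_invariant_to_time_translation(self, event_config,
                                                          geometry, rng):
        params = ScanpathParams(seed=2)
        pts = [rng.uniform([100, 100], [1300, 2700]) for _ in range(6)]
        sim = simulate_scanpath({"kind": "fixations", "points": pts}, params,
                                geometry, rng=rng)
        sm = bilateral_smooth(sim.trace, event_config)
        labels = classify_ivt(sm, event_config, geometry)
        n0 = len(extract_fixations(labels, sm, event_config))
        shifted = [GazeSample(s.t + 100.0, s.x, s.y, s.stage) for s in sm]
        labels2 = classify_ivt(shifted, event_config, geometry)
        n1 = len(extract_fixations(labels2, shifted, event_config))
        assert n0 == n1
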