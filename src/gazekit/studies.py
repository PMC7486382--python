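"""Desk-scale replication studies run entirely on synthetic data.

Each function reproduces one analysis of the pipeline end to end —
generate synthetic inputs with known ground truth, run the estimation or
detection machinery, and measure the result.  They are the package's
self-contained counterparts of the original experiments, scaled to sizes
that run in minutes on one CPU; all randomness derives from a single
seed.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .events import (EventConfig, bilateral_smooth, classify_ivt,
                     extract_events, extract_fixations, saccade_latency)
from .geometry import ScreenGeometry, degrees_to_cm
from .network import (GazeNetwork, NetworkConfig, TrainOptions,
                      train_base, _prepare_arrays, evaluate_arrays)
from .personalization import (PersonalizedModel, evaluate, fine_tune,
                              interleaved_split, subsample_calibration)
from .protocols import (fixations_to_target, generate_prosaccade_trial,
                        generate_pursuit_path, generate_search_display,
                        pursuit_tracking_error)
from .reading import difficulty_correlates, region_dwell_fraction, task_difficulty
from .saliency import SaliencyMap, blur, fixation_map, gaze_entropy, pixel_correlation
from .synth import (ScanpathParams, default_geometry, make_base_training_set,
                    make_calibration_session, make_user, simulate_reading_cohort,
                    simulate_scanpath)

__all__ = [
    "train_reference_base",
    "personalization_study",
    "fixation_recovery_study",
    "prosaccade_latency_study",
    "pursuit_lag_study",
    "search_study",
    "reading_difficulty_study",
    "entropy_task_contrast_study",
]


def train_reference_base(seed: int = 1, n_users: int = 20,
                         frames_per_user: int = 60, steps: int = 700,
                         g: Optional[ScreenGeometry] = None) -> Tuple[GazeNetwork, ScreenGeometry, float]:
    """Train the base network on a pooled synthetic-user cohort.

    Returns ``(net, geometry, training_error_cm)``.  The cohort size and
    per-user frame budget are desk-scale defaults chosen to train in a few
    CPU-minutes while spanning many screen positions and user biases; the
    optimiser's warmup and dead-unit revival (see
    :class:`~gazekit.network.TrainOptions`) keep training stable across
    initialisation seeds.
    """
    if g is None:
        g = default_geometry()
    dataset, _ = make_base_training_set(n_users=n_users,
                                        frames_per_user=frames_per_user,
                                        g=g, seed=seed)
    arrays = _prepare_arrays(dataset, g, 1.5)
    net = GazeNetwork(NetworkConfig(), seed=seed)
    train_base(net, [], g, TrainOptions(steps=steps, batch_size=16, lr=1e-3,
                                        seed=seed, eval_every=50), arrays=arrays)
    return net, g, evaluate_arrays(net, arrays)


def personalization_study(seed: int = 1, net: Optional[GazeNetwork] = None,
                          g: Optional[ScreenGeometry] = None,
                          session_frames: int = 400,
                          frame_counts: Sequence[int] = (10, 25, 50, 100),
                          n_subsample_seeds: int = 5,
                          fine_tune_steps: int = 150) -> Dict:
    """Personalization gain on a held-out synthetic user.

    Trains the base network if not supplied, renders a fresh user's
    calibration session, and reports the base model's hold-out error, the
    fully personalized error (per-user fine-tuning + SVR head on 100
    frames), and the head-only error as a function of calibration frame
    count averaged over subsample seeds.
    """
    if net is None:
        net, g, _ = train_reference_base(seed=seed)
    if g is None:
        g = default_geometry()
    user = make_user(seed * 7919 + 101, bias_sd_cm=0.8)
    records = make_calibration_session(session_frames, "dot", user, g,
                                       seed=seed * 31 + 7, n_markers=40,
                                       session_id="heldout")
    train, hold = interleaved_split(records)
    base_report = evaluate(net, hold, g)

    calib100 = subsample_calibration(train, 100, seed=seed)
    tuned = fine_tune(net, calib100, g,
                      TrainOptions(steps=fine_tune_steps, batch_size=16,
                                   lr=2e-4, seed=seed, patience=10,
                                   eval_every=15, warmup_steps=0,
                                   revive_every=0))
    personalized = PersonalizedModel.fit(tuned, calib100, g)
    pers_report = evaluate(personalized, hold, g)

    curve: Dict[int, float] = {}
    for n in frame_counts:
        errs = []
        for s in range(n_subsample_seeds):
            sub = subsample_calibration(train, n, seed=seed * 100 + s)
            model = PersonalizedModel.fit(net, sub, g)
            errs.append(evaluate(model, hold, g).mean_error_cm)
        curve[int(n)] = float(np.mean(errs))

    return {
        "user_bias_cm": user.per_user_bias_cm,
        "base_error_cm": base_report.mean_error_cm,
        "personalized_error_cm": pers_report.mean_error_cm,
        "error_reduction_factor": base_report.mean_error_cm
        / max(pers_report.mean_error_cm, 1e-9),
        "error_vs_frames_cm": curve,
    }


def fixation_recovery_study(seed: int = 0, n_trials: int = 100,
                            g: Optional[ScreenGeometry] = None,
                            cfg: EventConfig = EventConfig()) -> Dict:
    """Ground-truth fixation recovery of the detection pipeline.

    Simulates scanpaths of ten well-separated fixations each, runs
    smoothing + I-VT + extraction, and scores the fraction of ground-truth
    fixations (duration >= 150 ms) recovered with onset and offset within
    50 ms, plus any emitted fixation shorter than the 100 ms minimum.
    """
    if g is None:
        g = default_geometry()
    params = ScanpathParams(seed=seed)
    rng = np.random.default_rng(seed + 42)
    total = recovered = short_emitted = 0
    for _ in range(n_trials):
        pts: List[np.ndarray] = []
        while len(pts) < 10:
            p = rng.uniform([150, 150], [g.width_px - 150, g.height_px - 150])
            if not pts or np.linalg.norm(p - pts[-1]) > 300:
                pts.append(p)
        durs = np.clip(rng.lognormal(math.log(0.30), 0.3, 10), 0.16, 1.0)
        sim = simulate_scanpath({"kind": "fixations", "points": pts,
                                 "durations": list(durs)}, params, g, rng=rng)
        smoothed = bilateral_smooth(sim.trace, cfg)
        labels = classify_ivt(smoothed, cfg, g)
        detected = extract_fixations(labels, smoothed, cfg)
        for gt in sim.events:
            if gt.kind != "fixation" or gt.duration < 0.150:
                continue
            total += 1
            recovered += any(abs(d.onset - gt.onset) <= 0.050
                             and abs(d.offset - gt.offset) <= 0.050
                             for d in detected)
        short_emitted += sum(d.duration < cfg.min_fixation_ms / 1000.0
                             for d in detected)
    return {"recovery_rate": recovered / total, "n_ground_truth": total,
            "n_short_emitted": short_emitted}


def prosaccade_latency_study(seed: int = 11, n_trials: int = 200,
                             g: Optional[ScreenGeometry] = None,
                             cfg: EventConfig = EventConfig()) -> Dict:
    """Generate prosaccade trials at the 210 ms generative mean and
    recover latency through the detection pipeline."""
    if g is None:
        g = default_geometry()
    params = ScanpathParams(seed=seed)
    rng = np.random.default_rng(seed)
    gen, det = [], []
    for _ in range(n_trials):
        trial = generate_prosaccade_trial(g, rng)
        sim = simulate_scanpath(trial, params, g, rng=rng)
        gen.append(sim.truth["latency_ms"])
        smoothed = bilateral_smooth(sim.trace, cfg)
        lat = saccade_latency(smoothed, sim.truth["stimulus_onset_s"], cfg, g)
        if lat is not None:
            det.append(lat)
    return {"generated_mean_ms": float(np.mean(gen)),
            "generated_median_ms": float(np.median(gen)),
            "detected_mean_ms": float(np.mean(det)),
            "detected_median_ms": float(np.median(det)),
            "n_detected": len(det), "n_trials": n_trials}


def pursuit_lag_study(seed: int = 3, lag_ms: float = 100.0,
                      period_s: float = 8.0,
                      g: Optional[ScreenGeometry] = None) -> Dict:
    """Tracking error of a lagged pursuer on the 7-degree circle versus
    the closed-form chord ``2 r sin(pi L / T)``."""
    if g is None:
        g = default_geometry()
    path = generate_pursuit_path("circle", g, period_s=period_s, n_cycles=2)
    params = ScanpathParams(seed=seed, noise_sd_px=0.0, pursuit_lag_ms=lag_ms)
    sim = simulate_scanpath(path, params, g)
    measured = pursuit_tracking_error(sim.trace, path, g)
    r_cm = degrees_to_cm(7.0, g.viewing_distance_cm)
    predicted = 2 * r_cm * math.sin(math.pi * (lag_ms / 1000.0) / period_s)
    return {"measured_error_cm": measured, "predicted_error_cm": predicted,
            "relative_deviation": abs(measured - predicted) / predicted}


def search_study(seed: int = 5, n_trials: int = 200,
                 contrasts_deg: Sequence[float] = (7.0, 15.0, 75.0),
                 set_sizes: Sequence[int] = (5, 10, 15),
                 g: Optional[ScreenGeometry] = None,
                 cfg: EventConfig = EventConfig()) -> Dict:
    """Mean fixations-to-target across orientation contrast and set size.

    Runs the detection-probability searcher through the full event
    pipeline and scores search performance with
    :func:`~gazekit.protocols.fixations_to_target`.
    """
    if g is None:
        g = default_geometry()
    rng = np.random.default_rng(seed)
    means: Dict[Tuple[float, int], float] = {}
    for dtheta in contrasts_deg:
        for ss in set_sizes:
            counts = []
            for _ in range(n_trials):
                disp = generate_search_display(ss, "orientation", dtheta,
                                               int(rng.integers(1 << 30)), g)
                sim = simulate_scanpath(disp, ScanpathParams(seed=0), g, rng=rng)
                smoothed = bilateral_smooth(sim.trace, cfg)
                labels = classify_ivt(smoothed, cfg, g)
                events = extract_events(labels, smoothed, cfg, g)
                n, _ = fixations_to_target(events, disp)
                if n is not None:
                    counts.append(n)
            means[(float(dtheta), int(ss))] = float(np.mean(counts))
    return {"mean_fixations": means}


def reading_difficulty_study(seed: int = 0, n_tasks: int = 10) -> Dict:
    """Relevant-dwell share versus task difficulty on a synthetic cohort.

    Returns the per-task dwell shares, difficulties, and the Spearman
    correlation (with permutation p) between them.
    """
    fixmap, regmap, outcomes = simulate_reading_cohort(n_tasks=n_tasks, seed=seed)
    difficulty = task_difficulty(outcomes)
    dwell = {tid: region_dwell_fraction(fixmap[tid], regmap[tid])["relevant"]
             for tid in fixmap}
    rho, p = difficulty_correlates(dwell, difficulty, n_permutations=5000,
                                   seed=seed)
    return {"relevant_dwell_pct": dwell, "difficulty_pct": difficulty,
            "spearman_rho": rho, "permutation_p": p}


def entropy_task_contrast_study(seed: int = 0, n_images: int = 30,
                                shape: Tuple[int, int] = (128, 128)) -> Dict:
    """Gaze entropy of free-viewing versus search-style scanpaths.

    Free viewing draws fixations from several hotspots per image, search
    from a single target hotspot; both are blurred identically.
    """
    rng = np.random.default_rng(seed)
    free_H, search_H = [], []
    for _ in range(n_images):
        hotspots = rng.uniform(16, shape[0] - 16, (5, 2))
        free_pts = (hotspots[rng.integers(5, size=120)]
                    + rng.normal(0, 4, (120, 2)))
        search_pts = hotspots[0] + rng.normal(0, 4, (120, 2))
        free_H.append(gaze_entropy(blur(fixation_map(free_pts, shape), 4.0)))
        search_H.append(gaze_entropy(blur(fixation_map(search_pts, shape), 4.0)))
    return {"free_viewing_entropy_bits": float(np.mean(free_H)),
            "search_entropy_bits": float(np.mean(search_H)),
            "grid_shape": shape}
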