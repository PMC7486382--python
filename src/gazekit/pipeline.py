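"""End-to-end run orchestration: personalize, predict, detect, summarise.

A :class:`RunConfig` names the inputs (base checkpoint, calibration
session), the screen geometry and detection settings, the seed, and the
output directory.  :func:`run_pipeline` executes the stages in sequence —
fine-tune + SVR personalization, per-frame prediction, bilateral
smoothing, I-VT event detection, fixation heatmap — writing every
artifact with the config hash and seed stamped into ``run.json`` along
with per-stage input/output counts so the filtering rules (frames dropped
by the 800 ms onset discard, fixations dropped by the 100 ms minimum) are
auditable.  Input files are never mutated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from . import io as gio
from .events import EventConfig, bilateral_smooth, classify_ivt, extract_events
from .geometry import GazeSample, ScreenGeometry, Stage
from .network import GazeNetwork, TrainOptions
from .personalization import (PersonalizedModel, evaluate, fine_tune,
                              interleaved_split, subsample_calibration)
from .saliency import blur, fixation_map

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Raised with the failing stage's name and cause."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    screen: ScreenGeometry
    base_checkpoint: str
    session_path: str
    out_dir: str
    event: EventConfig = field(default_factory=EventConfig)
    seed: int = 0
    n_calibration_frames: int = 100
    fine_tune_steps: int = 200
    heatmap_blur_px: float = 24.0
    heatmap_downsample: int = 4  # grid cells of downsample x downsample px

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        return d


def run_pipeline(cfg: RunConfig) -> Dict:
    """Run the full pipeline; returns a result bundle of paths + metrics."""
    # -- validation up front, before any compute -----------------------
    for name, p in (("base_checkpoint", cfg.base_checkpoint),
                    ("session_path", cfg.session_path)):
        if not Path(p).exists():
            raise PipelineError("validate", f"missing {name}: {p}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": gio.config_hash(cfg.to_dict()), "seed": cfg.seed,
             "stages": {}}
    g = cfg.screen

    try:
        net = GazeNetwork.load(cfg.base_checkpoint)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("load_base", str(e)) from e

    try:
        records = gio.load_session(cfg.session_path)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("load_session", str(e)) from e
    stamp["stages"]["load_session"] = {"frames_read": len(records)}

    try:
        train, hold = interleaved_split(records)
        calib = subsample_calibration(train, cfg.n_calibration_frames, seed=cfg.seed)
        tuned = fine_tune(net, calib, g,
                          TrainOptions(steps=cfg.fine_tune_steps, batch_size=16,
                                       lr=3e-4, seed=cfg.seed, patience=10,
                                       warmup_steps=0, revive_every=0))
        model = PersonalizedModel.fit(tuned, calib, g)
        report = evaluate(model, hold, g)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("personalize", str(e)) from e
    stamp["stages"]["personalize"] = {
        "calibration_frames": len(calib), "holdout_frames": len(hold),
        "mean_error_cm": report.mean_error_cm,
    }
    (out / "error_report.json").write_text(json.dumps({
        "per_target_error_cm": list(report.per_target_error_cm),
        "mean_error_cm": report.mean_error_cm,
        "error_deg_at": {str(k): v for k, v in report.error_deg_at.items()},
    }, indent=2))

    try:
        frames = [r.frame for r in hold]
        est_px = model.predict_many(frames)
        trace = [  # personalized per-frame trace on the hold-out frames
            GazeSample(f.t, float(p[0]), float(p[1]), stage=Stage.PERSONALIZED)
            for f, p in zip(frames, est_px)
        ]
        trace.sort(key=lambda s: s.t)
        gio.save_trace(trace, out / "trace.csv")
        smoothed = bilateral_smooth(trace, cfg.event)
        labels = classify_ivt(smoothed, cfg.event, g)
        events = extract_events(labels, smoothed, cfg.event, g)
        gio.save_events(events, out / "events.csv")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("events", str(e)) from e
    n_fix = sum(e.kind == "fixation" for e in events)
    stamp["stages"]["events"] = {"samples_in": len(trace), "fixations": n_fix,
                                 "saccades": len(events) - n_fix}

    try:
        ds = max(int(cfg.heatmap_downsample), 1)
        fixes = [e for e in events if e.kind == "fixation"]
        pts = [(e.centroid[0] / ds, e.centroid[1] / ds) for e in fixes]
        fmap = fixation_map(pts, (g.height_px // ds, g.width_px // ds))
        heat = blur(fmap, cfg.heatmap_blur_px / ds) if not fmap.is_empty else fmap
        gio.save_heatmap_csv(heat, out / "heatmap.csv")
        gio.save_heatmap_png(heat, out / "heatmap.png")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("heatmap", str(e)) from e
    stamp["stages"]["heatmap"] = {"fixations_in": len(fixes),
                                  "blur_px": cfg.heatmap_blur_px}

    (out / "run.json").write_text(json.dumps(stamp, indent=2))
    return {"error_report": report, "events": events, "out_dir": str(out),
            "stamp": stamp}
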