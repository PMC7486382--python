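"""Readers and writers for sessions, traces, events and heatmaps.

Frame-indexed data use JSON-lines (one record per camera frame), time
series and tables use CSV with units embedded in the column names, and
images use PNG.  Everything is greppable and diffable on purpose.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .events import EventConfig, OculomotorEvent
from .geometry import GazeSample, ScreenGeometry, Stage
from .network import EyeFrame
from .personalization import CalibrationRecord
from .saliency import SaliencyMap

__all__ = [
    "save_session",
    "load_session",
    "save_trace",
    "load_trace",
    "save_events",
    "load_events",
    "save_heatmap_csv",
    "save_heatmap_png",
    "load_config",
    "config_hash",
]

_SESSION_FIELDS = ("t_sec", "frame_path", "landmarks", "marker_x_px", "marker_y_px",
                   "session_id")


def save_session(records: Sequence[CalibrationRecord], out_dir) -> Path:
    """Write a calibration session as PNG frames + a JSON-lines index."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = out_dir / "session.jsonl"
    with open(index, "w") as fh:
        for i, rec in enumerate(records):
            name = f"frame_{i:05d}.png"
            img8 = (np.clip(rec.frame.image, 0, 1) * 255).astype(np.uint8)
            Image.fromarray(img8).save(out_dir / name)
            fh.write(json.dumps({
                "t_sec": rec.frame.t,
                "frame_path": name,
                "landmarks": rec.frame.landmarks.tolist(),
                "marker_x_px": float(rec.marker[0]),
                "marker_y_px": float(rec.marker[1]),
                "session_id": rec.session_id,
            }) + "\n")
    return index


def load_session(path) -> List[CalibrationRecord]:
    """Load a JSON-lines calibration session, validating each line.

    Malformed lines are reported with their line number and the missing
    or invalid field.
    """
    path = Path(path)
    base = path.parent
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as e:
                raise ValueError(f"line {lineno}: invalid JSON ({e})") from None
            for fld in _SESSION_FIELDS:
                if fld not in obj:
                    raise ValueError(f"line {lineno}: missing field '{fld}'")
            img = np.asarray(Image.open(base / obj["frame_path"]), dtype=np.float32) / 255.0
            if img.ndim == 2:
                img = np.repeat(img[:, :, None], 3, axis=2)
            lm = np.asarray(obj["landmarks"], dtype=float)
            if lm.shape != (4, 2):
                raise ValueError(f"line {lineno}: field 'landmarks' must be 4x2")
            frame = EyeFrame(image=img[:, :, :3], landmarks=lm, t=float(obj["t_sec"]))
            records.append(CalibrationRecord(
                frame=frame,
                marker=np.array([obj["marker_x_px"], obj["marker_y_px"]], dtype=float),
                session_id=str(obj["session_id"]),
            ))
    return records


def save_trace(trace: Sequence[GazeSample], path) -> None:
    df = pd.DataFrame({
        "t_sec": [s.t for s in trace],
        "x_px": [s.x for s in trace],
        "y_px": [s.y for s in trace],
        "stage": [s.stage.value for s in trace],
    })
    df.to_csv(path, index=False)


def load_trace(path) -> List[GazeSample]:
    df = pd.read_csv(path)
    for col in ("t_sec", "x_px", "y_px"):
        if col not in df.columns:
            raise ValueError(f"trace file missing column '{col}'")
    stages = df["stage"] if "stage" in df.columns else ["raw"] * len(df)
    return [GazeSample(float(t), float(x), float(y), Stage(st))
            for t, x, y, st in zip(df["t_sec"], df["x_px"], df["y_px"], stages)]


def save_events(events: Sequence[OculomotorEvent], path) -> None:
    rows = []
    for e in events:
        rows.append({
            "kind": e.kind,
            "onset_sec": e.onset,
            "offset_sec": e.offset,
            "x_px": e.centroid[0] if e.centroid else np.nan,
            "y_px": e.centroid[1] if e.centroid else np.nan,
            "amplitude_deg": e.amplitude_deg if e.amplitude_deg is not None else np.nan,
        })
    pd.DataFrame(rows, columns=["kind", "onset_sec", "offset_sec",
                                "x_px", "y_px", "amplitude_deg"]).to_csv(path, index=False)


def load_events(path) -> List[OculomotorEvent]:
    df = pd.read_csv(path)
    events = []
    for _, row in df.iterrows():
        centroid = None
        if not (pd.isna(row["x_px"]) or pd.isna(row["y_px"])):
            centroid = (float(row["x_px"]), float(row["y_px"]))
        amp = None if pd.isna(row["amplitude_deg"]) else float(row["amplitude_deg"])
        events.append(OculomotorEvent(row["kind"], float(row["onset_sec"]),
                                      float(row["offset_sec"]), centroid=centroid,
                                      amplitude_deg=amp))
    return events


def save_heatmap_csv(smap: SaliencyMap, path) -> None:
    """Exact grid values; the header records blur and fixation count."""
    with open(path, "w") as fh:
        fh.write(f"# saliency grid, units=fixation_mass, blur_px={smap.blur_px}, "
                 f"n_fixations={smap.n_fixations}\n")
        np.savetxt(fh, smap.grid, delimiter=",", fmt="%.8g")


def save_heatmap_png(smap: SaliencyMap, path) -> None:
    grid = smap.grid
    top = grid.max()
    img = (grid / top * 255 if top > 0 else grid).astype(np.uint8)
    Image.fromarray(img).save(path)


def load_config(path) -> Dict:
    """Load a YAML run config; returns typed blocks where recognised."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = dict(raw)
    if "screen" in raw:
        out["screen"] = ScreenGeometry(**raw["screen"])
    if "event" in raw:
        out["event"] = EventConfig(**raw["event"])
    return out


def config_hash(cfg: Dict) -> str:
    """Stable short hash stamped into every pipeline artifact."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
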