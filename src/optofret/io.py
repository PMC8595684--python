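"""Readers and writers: OME-TIFF stacks, ground-truth sidecars, CSV logs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import DualChannelStack, StimulusEvent
from .segmentation import CellTrack, LabelStack
from .synthetic import (CellTruth, GroundTruthScene, KineticsParams,
                        SceneParams)

STIM_LOG_COLUMNS = ["frame", "t_s", "event", "power_uW",
                    "target_row", "target_col", "stage_dx_um", "stage_dy_um"]


# ---------------------------------------------------------------------------
# Dual-channel stacks
# ---------------------------------------------------------------------------

def write_stack(out_dir: str | Path, stack: DualChannelStack,
                prefix: str = "") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"axes": "TYX",
            "PhysicalSizeX": stack.pixel_size,
            "PhysicalSizeY": stack.pixel_size,
            "TimeIncrement": stack.frame_interval}
    for name, arr in (("donor", stack.donor), ("acceptor", stack.acceptor)):
        tifffile.imwrite(out / f"{prefix}{name}.ome.tif",
                         np.asarray(arr), metadata=meta,
                         photometric="minisblack")
    sidecar = {
        "pixel_size": stack.pixel_size,
        "frame_interval": stack.frame_interval,
        "stimuli": [s.to_dict() for s in stack.stimuli],
        "meta": _jsonable(stack.meta),
    }
    with open(out / f"{prefix}stack.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_stack(in_dir: str | Path, prefix: str = "") -> DualChannelStack:
    in_dir = Path(in_dir)
    donor = tifffile.imread(in_dir / f"{prefix}donor.ome.tif")
    acceptor = tifffile.imread(in_dir / f"{prefix}acceptor.ome.tif")
    with open(in_dir / f"{prefix}stack.json") as fh:
        side = json.load(fh)
    return DualChannelStack(
        donor=donor, acceptor=acceptor,
        pixel_size=side["pixel_size"],
        frame_interval=side["frame_interval"],
        stimuli=[StimulusEvent.from_dict(d) for d in side["stimuli"]],
        meta=side.get("meta", {}))


# ---------------------------------------------------------------------------
# Ground-truth scenes
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def scene_params_to_dict(params: SceneParams) -> dict:
    d = dataclasses.asdict(params)
    d["field_shape"] = list(params.field_shape)
    d["kinetics"] = dataclasses.asdict(params.kinetics)
    d["stimuli"] = [s.to_dict() for s in params.stimuli]
    return _jsonable(d)


def scene_params_from_dict(d: dict) -> SceneParams:
    d = dict(d)
    d["field_shape"] = tuple(d["field_shape"])
    d["kinetics"] = KineticsParams(**d["kinetics"])
    d["stimuli"] = [StimulusEvent.from_dict(s) for s in d["stimuli"]]
    return SceneParams(**d)


def write_scene(out_dir: str | Path, scene: GroundTruthScene) -> None:
    """Ground-truth sidecar: tracks, activity, optics-independent truth,
    stimulus log, config echo, plus the label stack as TIFF."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "labels.tif",
                     scene.label_stack.astype(np.int16),
                     photometric="minisblack")
    cells = []
    for c in scene.cells:
        cells.append({
            "index": c.index,
            "centroids_um": c.centroids_um.tolist(),
            "radius_um": c.radius_um,
            "boundary_amp": c.boundary_amp.tolist(),
            "boundary_phase": c.boundary_phase.tolist(),
            "baseline_ratio": c.baseline_ratio,
            "sensor_density": c.sensor_density,
            "is_dead": c.is_dead,
            "activity": c.activity.tolist(),
            "activity_ndim": int(c.activity.ndim),
            "bbox": None if c.bbox is None else list(c.bbox),
        })
    doc = {
        "field_shape": list(scene.field_shape),
        "pixel_size": scene.pixel_size,
        "frame_interval": scene.frame_interval,
        "n_frames": scene.n_frames,
        "seed": scene.seed,
        "stimuli": [s.to_dict() for s in scene.stimuli],
        "cells": cells,
        "params": None if scene.params is None
        else scene_params_to_dict(scene.params),
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(doc, fh)


def read_scene(in_dir: str | Path) -> GroundTruthScene:
    in_dir = Path(in_dir)
    with open(in_dir / "ground_truth.json") as fh:
        doc = json.load(fh)
    labels = tifffile.imread(in_dir / "labels.tif")
    if labels.ndim == 2:
        labels = labels[None]
    cells = []
    for c in doc["cells"]:
        cells.append(CellTruth(
            index=c["index"],
            centroids_um=np.asarray(c["centroids_um"]),
            radius_um=c["radius_um"],
            boundary_amp=np.asarray(c["boundary_amp"]),
            boundary_phase=np.asarray(c["boundary_phase"]),
            baseline_ratio=c["baseline_ratio"],
            sensor_density=c["sensor_density"],
            is_dead=c["is_dead"],
            activity=np.asarray(c["activity"]),
            bbox=None if c["bbox"] is None else tuple(c["bbox"])))
    params = (None if doc["params"] is None
              else scene_params_from_dict(doc["params"]))
    return GroundTruthScene(
        cells=cells, field_shape=tuple(doc["field_shape"]),
        pixel_size=doc["pixel_size"], frame_interval=doc["frame_interval"],
        n_frames=doc["n_frames"], stimuli=[StimulusEvent.from_dict(s)
                                           for s in doc["stimuli"]],
        seed=doc["seed"], label_stack=np.asarray(labels, dtype=np.int16),
        params=params)


# ---------------------------------------------------------------------------
# Stimulus/stage logs and track tables
# ---------------------------------------------------------------------------

def write_stim_log(path: str | Path, rows: list[dict]) -> None:
    pd.DataFrame(rows, columns=STIM_LOG_COLUMNS).to_csv(path, index=False)


def read_stim_log(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(STIM_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"stimulus log missing columns: {sorted(missing)}")
    return df


def tracks_to_dataframe(stack: LabelStack,
                        tracks: list[CellTrack]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for frame, lab in zip(tr.frames, tr.labels):
            obj = next(o for o in stack.objects[frame] if o.label == lab)
            rows.append({
                "track_id": tr.track_id,
                "frame": frame,
                "centroid_x_um": obj.centroid_px[1] * stack.pixel_size,
                "centroid_y_um": obj.centroid_px[0] * stack.pixel_size,
                "area_px": obj.area_px,
                "complete": tr.complete,
                "qc": ";".join(f"{k}={v}" for k, v in sorted(tr.qc.items())),
            })
    return pd.DataFrame(rows)
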