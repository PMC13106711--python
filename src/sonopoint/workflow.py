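"""Composed pipeline: simulate -> augment -> filter -> measure -> evaluate.

The tracking workflow is a chain of data operations: sparse manual labels
are densified into per-frame labels, per-frame anchors (from any keypoint
model, an imported keypoint table, or the phantom's noisy-anchor simulator)
are jitter-filtered against the video, trajectories become scalar
measurements, and candidates are scored against ground truth.  The deep
learning stage of the original workflow is represented by a pluggable
anchor source: any per-frame trajectory layer serves as anchors.

Every run writes a manifest (inputs, config hash, package versions, seed);
identical config + seed reproduce all artifacts bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import os
import tomllib
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from . import __version__
from .annotations import (
    AnnotationLayer,
    layer_from_trajectories,
    load_layer,
    save_layer,
    trajectories_from_layer,
)
from .augment import densify_layer
from .evalsuite import band_power, rmse
from .jitter_filter import RSTCFilterConfig, filter_trajectories
from .lkrstc import LKConfig
from .measures import MeasurementSpec, deformation_series, fascicle_metrics, pair_distance_series
from .media_io import load_video, save_video
from .phantom import make_scene, simulate_anchor_noise

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "STAGES"]

STAGES = ("simulate", "augment", "filter", "measure", "evaluate")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, loadable from a TOML file.

    Path fields may be filled by earlier stages (e.g. ``simulate`` provides
    the video and anchors consumed by ``filter``).
    """

    out_dir: str = "sonopoint_out"
    seed: int = 0
    pixel_pitch: float | None = None

    video: str | None = None
    layer: str | None = None        # sparse manual annotations (augment input)
    anchors: str | None = None      # per-frame anchor layer (filter input)
    trajectories: str | None = None  # dense layer for measure (default: filter output)
    truth: str | None = None        # ground-truth layer (evaluate reference)
    candidates: list[str] = field(default_factory=list)

    lk: LKConfig = field(default_factory=LKConfig)
    filter: RSTCFilterConfig = field(default_factory=RSTCFilterConfig)
    steepness: float = 10.0
    phantom: dict[str, Any] = field(default_factory=dict)
    measures: list[dict[str, Any]] = field(default_factory=list)


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Read a TOML config with optional [lk], [filter], [phantom],
    [[measures]] sections and top-level path/seed keys."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    lk = LKConfig(**doc.get("lk", {}))
    filt_doc = dict(doc.get("filter", {}))
    filt_doc.setdefault("steepness", doc.get("rstc", {}).get("steepness", 10.0))
    filt = RSTCFilterConfig(lk=lk, **filt_doc)
    known = {
        k: doc[k]
        for k in (
            "out_dir", "seed", "pixel_pitch", "video", "layer", "anchors",
            "trajectories", "truth", "candidates",
        )
        if k in doc
    }
    return PipelineConfig(
        lk=lk,
        filter=filt,
        steepness=filt.steepness,
        phantom=doc.get("phantom", {}),
        measures=doc.get("measures", []),
        **known,
    )


def _config_hash(cfg: PipelineConfig) -> str:
    doc = asdict(cfg)
    blob = json.dumps(doc, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig, stages: list[str]) -> dict[str, Any]:
    """Execute the requested stages in workflow order.

    Returns (and writes to ``out_dir/manifest.json``) a manifest describing
    each stage's artifacts.  Raises with the missing artifact's name when a
    stage's dependency is unsatisfied, and on unknown stage names.
    """
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; valid stages: {list(STAGES)}")
    stages = [s for s in STAGES if s in stages]  # canonical order
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "versions": {"sonopoint": __version__, "numpy": np.__version__},
        "stages": {},
    }

    def out(name: str) -> str:
        return os.path.join(cfg.out_dir, name)

    for stage in stages:
        if stage == "simulate":
            params = dict(cfg.phantom)
            kind = params.pop("kind", "sinusoid")
            scene = make_scene(kind, seed=cfg.seed, **params)
            video_path = out("scene.npz")
            save_video(scene.clip, video_path)
            truth_layer = layer_from_trajectories(scene.truth, name="truth")
            truth_path = save_layer(truth_layer, out("truth.json"))
            noisy = simulate_anchor_noise(scene.truth, seed=cfg.seed + 1)
            anchors_path = save_layer(
                layer_from_trajectories(noisy, name="anchors"), out("anchors.json")
            )
            cfg.video = cfg.video or video_path
            cfg.truth = cfg.truth or truth_path
            cfg.anchors = cfg.anchors or anchors_path
            manifest["stages"]["simulate"] = {
                "video": video_path, "truth": truth_path, "anchors": anchors_path,
            }

        elif stage == "augment":
            _require(cfg.video, "video", stage)
            _require(cfg.layer, "layer (sparse annotations)", stage)
            clip = load_video(cfg.video)
            dense = densify_layer(clip, load_layer(cfg.layer), cfg.lk, cfg.steepness)
            path = save_layer(dense, out("augmented.json"))
            cfg.anchors = cfg.anchors or path
            manifest["stages"]["augment"] = {"layer": path}

        elif stage == "filter":
            _require(cfg.video, "video", stage)
            _require(cfg.anchors, "anchors", stage)
            clip = load_video(cfg.video)
            anchors = trajectories_from_layer(load_layer(cfg.anchors), fps=clip.fps)
            filtered = filter_trajectories(clip, anchors, cfg.filter)
            path = save_layer(
                layer_from_trajectories(filtered, name="filtered"), out("filtered.json")
            )
            cfg.trajectories = cfg.trajectories or path
            manifest["stages"]["filter"] = {"layer": path}

        elif stage == "measure":
            _require(cfg.trajectories, "trajectories", stage)
            _require(cfg.measures, "measures (config [[measures]] sections)", stage)
            layer = load_layer(cfg.trajectories)
            trajs = {t.label_id: t for t in trajectories_from_layer(layer)}
            columns: dict[str, np.ndarray] = {}
            fps = next(iter(trajs.values())).fps
            for mdoc in cfg.measures:
                spec = MeasurementSpec(
                    kind=mdoc["kind"],
                    roles={k: int(v) for k, v in mdoc["roles"].items()},
                    reference_frame=int(mdoc.get("reference_frame", 0)),
                    name=mdoc.get("name", mdoc["kind"]),
                )
                if spec.kind == "fascicle":
                    length, penn = fascicle_metrics(trajs, spec, cfg.pixel_pitch)
                    columns[length.name] = length.values
                    columns[penn.name] = penn.values
                else:
                    dist = pair_distance_series(
                        trajs[spec.roles["a"]], trajs[spec.roles["b"]],
                        cfg.pixel_pitch, name=spec.name,
                    )
                    columns[dist.name] = dist.values
                    if spec.kind == "deformation":
                        deform = deformation_series(dist, spec.reference_frame)
                        columns[deform.name] = deform.values
            import pandas as pd

            n = len(next(iter(columns.values())))
            df = pd.DataFrame({"frame": np.arange(n), "time_s": np.arange(n) / fps, **columns})
            path = out("measures.csv")
            df.to_csv(path, index=False)
            manifest["stages"]["measure"] = {"table": path}

        elif stage == "evaluate":
            _require(cfg.truth, "truth", stage)
            candidates = list(cfg.candidates) or (
                [cfg.trajectories] if cfg.trajectories else []
            )
            _require(candidates, "candidates", stage)
            truth = {t.label_id: t for t in trajectories_from_layer(load_layer(cfg.truth))}
            rows = []
            for cand_path in candidates:
                cand = trajectories_from_layer(load_layer(cand_path))
                errs, hf = [], []
                for traj in cand:
                    ref = truth[traj.label_id]
                    errs.append(rmse(ref, traj))
                    residual = traj.with_positions(traj.positions - ref.positions)
                    hf.append(band_power(residual, 2.0, 10.0))
                row = {
                    "candidate": os.path.basename(cand_path),
                    "rmse_px": float(np.mean(errs)),
                    "hf_power_2_10Hz": float(np.mean(hf)),
                }
                if cfg.pixel_pitch:
                    row["rmse_um"] = row["rmse_px"] * cfg.pixel_pitch
                rows.append(row)
            import pandas as pd

            path = out("report.csv")
            pd.DataFrame(rows).to_csv(path, index=False)
            manifest["stages"]["evaluate"] = {"report": path}

    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _require(value, name: str, stage: str) -> None:
    if not value:
        raise ValueError(f"stage '{stage}' requires '{name}' but it is absent")
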