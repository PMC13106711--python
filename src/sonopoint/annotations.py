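"""Sparse point annotations organised into named layers.

An annotation layer maps frame indices to sets of labelled points.  Layers
are the unit of interchange between manual labelling, optical-flow
augmentation, external per-frame keypoint models and the jitter filter.

Persistence formats:

* JSON — the native, human-readable format.  Schema::

      {"name": str, "fps": number|null,
       "labels": {"<frame>": [[label_id, x, y], ...], ...}}

  Frame keys are decimal strings; coordinates are floats (pixels).

* keypoint CSV — the three-header-row table dialect used by markerless
  pose-estimation tools (scorer / bodyparts / coords rows, one data row per
  frame, an x,y column pair per point, missing labels as empty cells).
"""

from __future__ import annotations

import json
import math
import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import Trajectory

__all__ = [
    "PointLabel",
    "AnnotationLayer",
    "save_layer",
    "load_layer",
    "trim_layer",
    "merge_range",
    "export_keypoint_table",
    "import_keypoint_table",
    "layer_from_trajectories",
    "trajectories_from_layer",
]


@dataclass(frozen=True)
class PointLabel:
    """One labelled point: numeric id plus sub-pixel position."""

    label_id: int
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.label_id < 0:
            raise ValueError(f"label_id must be >= 0, got {self.label_id}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"coordinates must be finite, got ({self.x}, {self.y})")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=np.float64)


@dataclass
class AnnotationLayer:
    """A named, possibly sparse frame -> point-labels mapping.

    ``labels`` maps frame index to a dict ``label_id -> PointLabel``; gaps
    between annotated frames are allowed.  Within one frame each label_id
    appears at most once.
    """

    name: str = "layer"
    labels: dict[int, dict[int, PointLabel]] = field(default_factory=dict)
    fps: float | None = None

    def __post_init__(self) -> None:
        for frame in self.labels:
            if frame < 0:
                raise ValueError(f"negative frame index {frame} in layer '{self.name}'")

    # -- mutation ----------------------------------------------------------
    def add(self, frame: int, label: PointLabel) -> None:
        if frame < 0:
            raise ValueError(f"negative frame index {frame}")
        self.labels.setdefault(frame, {})[label.label_id] = label

    def get(self, frame: int, label_id: int) -> PointLabel | None:
        return self.labels.get(frame, {}).get(label_id)

    # -- views -------------------------------------------------------------
    @property
    def frames(self) -> list[int]:
        return sorted(self.labels)

    @property
    def label_ids(self) -> set[int]:
        out: set[int] = set()
        for frame_labels in self.labels.values():
            out.update(frame_labels)
        return out

    @property
    def n_entries(self) -> int:
        return sum(len(v) for v in self.labels.values())

    def frames_of(self, label_id: int) -> list[int]:
        """Sorted frames on which ``label_id`` is annotated."""
        return sorted(f for f, fl in self.labels.items() if label_id in fl)

    def copy(self, name: str | None = None) -> "AnnotationLayer":
        return AnnotationLayer(
            name=name if name is not None else self.name,
            labels={f: dict(fl) for f, fl in self.labels.items()},
            fps=self.fps,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationLayer):
            return NotImplemented
        return (
            self.name == other.name
            and self.fps == other.fps
            and {f: fl for f, fl in self.labels.items() if fl}
            == {f: fl for f, fl in other.labels.items() if fl}
        )


# ---------------------------------------------------------------------------
# JSON persistence
# ---------------------------------------------------------------------------

def save_layer(layer: AnnotationLayer, path: str | os.PathLike) -> str:
    """Write a layer to human-readable JSON (see module docstring schema)."""
    path = os.fspath(path)
    doc = {
        "name": layer.name,
        "fps": layer.fps,
        "labels": {
            str(frame): [
                [lbl.label_id, lbl.x, lbl.y]
                for lbl in sorted(frame_labels.values(), key=lambda p: p.label_id)
            ]
            for frame, frame_labels in sorted(layer.labels.items())
            if frame_labels
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    return path


def load_layer(path: str | os.PathLike) -> AnnotationLayer:
    """Read a layer saved by :func:`save_layer`, enforcing invariants."""
    path = os.fspath(path)
    with open(path) as fh:
        doc = json.load(fh)

    labels: dict[int, dict[int, PointLabel]] = {}
    for frame_key, entries in doc.get("labels", {}).items():
        frame = int(frame_key)
        if frame < 0:
            raise ValueError(f"{path}: negative frame key {frame_key!r}")
        frame_labels: dict[int, PointLabel] = {}
        for label_id, x, y in entries:
            label_id = int(label_id)
            if label_id in frame_labels:
                raise ValueError(
                    f"{path}: duplicate label_id {label_id} in frame {frame}"
                )
            frame_labels[label_id] = PointLabel(label_id, float(x), float(y))
        labels[frame] = frame_labels
    return AnnotationLayer(name=doc.get("name", "layer"), labels=labels, fps=doc.get("fps"))


# ---------------------------------------------------------------------------
# layer algebra
# ---------------------------------------------------------------------------

def trim_layer(layer: AnnotationLayer) -> AnnotationLayer:
    """Keep only frames on which *every* label_id in the layer is annotated.

    "Complete frames only": a frame survives iff it carries all label_ids
    that appear anywhere in the layer.  Idempotent; the input is untouched.
    """
    all_ids = layer.label_ids
    kept = {
        frame: dict(frame_labels)
        for frame, frame_labels in layer.labels.items()
        if set(frame_labels) == all_ids and frame_labels
    }
    return AnnotationLayer(name=layer.name, labels=kept, fps=layer.fps)


def merge_range(
    src: AnnotationLayer,
    dst: AnnotationLayer,
    frames: tuple[int, int],
    label_ids: set[int] | None = None,
) -> AnnotationLayer:
    """Copy ``src`` entries for ``frames=[start, stop)`` x ``label_ids`` into
    a copy of ``dst``.  Selected src entries overwrite dst; everything outside
    the selection is untouched.  ``label_ids=None`` selects all of src's ids.
    """
    start, stop = frames
    ids = src.label_ids if label_ids is None else set(label_ids)
    out = dst.copy()
    for frame, frame_labels in src.labels.items():
        if start <= frame < stop:
            for label_id, lbl in frame_labels.items():
                if label_id in ids:
                    out.add(frame, lbl)
    return out


# ---------------------------------------------------------------------------
# keypoint-table interchange (3-header-row CSV dialect)
# ---------------------------------------------------------------------------

def export_keypoint_table(
    layer: AnnotationLayer, path: str | os.PathLike, scorer: str = "sonopoint"
) -> str:
    """Write the layer as a 3-header-row keypoint CSV.

    Header rows are scorer / bodyparts / coords; each point contributes an
    x,y column pair named ``pt<label_id>``; one data row per annotated frame;
    missing labels become empty cells.
    """
    if layer.n_entries == 0:
        raise ValueError("cannot export an empty layer")
    path = os.fspath(path)
    ids = sorted(layer.label_ids)
    frames = layer.frames
    columns = pd.MultiIndex.from_tuples(
        [(scorer, f"pt{i}", c) for i in ids for c in ("x", "y")],
        names=["scorer", "bodyparts", "coords"],
    )
    data = np.full((len(frames), 2 * len(ids)), np.nan)
    for r, frame in enumerate(frames):
        for c, label_id in enumerate(ids):
            lbl = layer.get(frame, label_id)
            if lbl is not None:
                data[r, 2 * c] = lbl.x
                data[r, 2 * c + 1] = lbl.y
    df = pd.DataFrame(data, index=pd.Index(frames), columns=columns)
    df.to_csv(path, na_rep="")
    return path


def _parse_label_id(bodypart: str, fallback: int) -> int:
    m = re.search(r"(\d+)\s*$", str(bodypart))
    return int(m.group(1)) if m else fallback


def import_keypoint_table(path: str | os.PathLike, name: str | None = None) -> AnnotationLayer:
    """Read a 3-header-row keypoint table (CSV, or HDF5 when pandas' HDF
    support is available).  Likelihood columns are accepted and ignored;
    NaN or empty cells mean "label absent on that frame"."""
    path = os.fspath(path)
    if path.endswith((".h5", ".hdf5")):
        df = pd.read_hdf(path)
    else:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    if df.columns.nlevels != 3:
        raise ValueError(
            f"{path}: expected 3 header rows (scorer/bodyparts/coords), "
            f"found {df.columns.nlevels}"
        )

    layer = AnnotationLayer(name=name if name is not None else os.path.basename(path))
    bodyparts = list(dict.fromkeys(col[1] for col in df.columns))
    id_of = {bp: _parse_label_id(bp, i) for i, bp in enumerate(bodyparts)}
    for frame_key, row in df.iterrows():
        frame = int(frame_key)
        for bp in bodyparts:
            scorer = df.columns[0][0]
            try:
                x = float(row[(scorer, bp, "x")])
                y = float(row[(scorer, bp, "y")])
            except KeyError as exc:
                raise ValueError(f"{path}: malformed header, missing {exc}") from exc
            if math.isfinite(x) and math.isfinite(y):
                layer.add(frame, PointLabel(id_of[bp], x, y))
    return layer


# ---------------------------------------------------------------------------
# trajectory <-> layer bridging
# ---------------------------------------------------------------------------

def layer_from_trajectories(
    trajectories: list[Trajectory], name: str = "trajectories"
) -> AnnotationLayer:
    """Flatten dense trajectories into an annotation layer."""
    fps = trajectories[0].fps if trajectories else None
    layer = AnnotationLayer(name=name, fps=fps)
    for traj in trajectories:
        for offset, (x, y) in enumerate(traj.positions):
            layer.add(traj.first_frame + offset, PointLabel(traj.label_id, float(x), float(y)))
    return layer


def trajectories_from_layer(
    layer: AnnotationLayer, fps: float | None = None, pixel_pitch: float | None = None
) -> list[Trajectory]:
    """Extract one contiguous Trajectory per label_id.

    Each label must be annotated on every frame between its first and last
    annotated frame (i.e. the layer is dense for that label); gaps raise.
    """
    out: list[Trajectory] = []
    use_fps = fps if fps is not None else (layer.fps if layer.fps else 50.0)
    for label_id in sorted(layer.label_ids):
        frames = layer.frames_of(label_id)
        first, last = frames[0], frames[-1]
        if len(frames) != last - first + 1:
            missing = sorted(set(range(first, last + 1)) - set(frames))
            raise ValueError(
                f"label {label_id} is not dense: missing frames {missing[:5]}"
                f"{'...' if len(missing) > 5 else ''}"
            )
        positions = np.array(
            [layer.get(f, label_id).xy for f in range(first, last + 1)]  # type: ignore[union-attr]
        )
        out.append(
            Trajectory(
                label_id=label_id,
                positions=positions,
                fps=use_fps,
                first_frame=first,
                pixel_pitch=pixel_pitch,
            )
        )
    return out
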