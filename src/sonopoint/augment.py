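"""Sparse-label densification via LK-RSTC.

Manual annotation of ultrasound video is done on a sparse subset of frames
(typically ~25 labels across a ~500-frame span).  Densification fills every
frame between consecutive manual labels by running one LK-RSTC window per
inter-annotation gap, anchored at the two manual labels.  Manual labels
always pass through exactly — densification never overwrites them — and no
extrapolation happens before a label's first or after its last annotation
(LK-RSTC needs two anchors).
"""

from __future__ import annotations

import warnings

import numpy as np

from .annotations import AnnotationLayer, PointLabel
from .lkrstc import LKConfig, rstc_interpolate
from .media_io import VideoClip

__all__ = ["densify_layer"]


def densify_layer(
    clip: VideoClip,
    sparse: AnnotationLayer,
    cfg: LKConfig | None = None,
    steepness: float = 10.0,
) -> AnnotationLayer:
    """Fill intermediate frames between annotated frames with LK-RSTC.

    Per label, every consecutive pair of annotated frames with at least one
    frame between them becomes an independent LK-RSTC window anchored at the
    two manual positions.  Labels annotated on fewer than two frames are
    skipped with a warning; an annotation beyond the clip raises.

    The result is dense per label over its annotated span, idempotent under
    re-densification, and exactly preserves all input annotations.
    """
    cfg = cfg or LKConfig()
    out = sparse.copy(name=f"{sparse.name}_densified")
    if sparse.labels and max(sparse.frames) >= clip.frame_count:
        raise ValueError(
            f"annotation on frame {max(sparse.frames)} but the clip has only "
            f"{clip.frame_count} frames"
        )

    for label_id in sorted(sparse.label_ids):
        frames = sparse.frames_of(label_id)
        if len(frames) < 2:
            warnings.warn(
                f"label {label_id} has {len(frames)} annotated frame(s); "
                "densification needs >= 2 — skipped",
                stacklevel=2,
            )
            continue
        for a, b in zip(frames[:-1], frames[1:]):
            if b - a < 2:
                continue  # adjacent annotations: no intermediate frames
            start = sparse.get(a, label_id).xy  # type: ignore[union-attr]
            end = sparse.get(b, label_id).xy  # type: ignore[union-attr]
            tracklet = rstc_interpolate(
                clip, a, b, start_anchor=start, end_anchor=end,
                cfg=cfg, steepness=steepness,
            )
            for frame, pos, ok in zip(
                tracklet.intermediate_frames, tracklet.fused[:, 0, :], tracklet.status[:, 0]
            ):
                if not ok:
                    # fall back to linear interpolation between the anchors
                    alpha = (frame - a) / (b - a)
                    pos = (1 - alpha) * start + alpha * end
                if out.get(int(frame), label_id) is None:  # never touch manual labels
                    out.add(int(frame), PointLabel(label_id, float(pos[0]), float(pos[1])))
    return out
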