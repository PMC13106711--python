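"""Transposed sliding-window jitter filter.

Per-frame keypoint detectors (CNNs) localise points independently in every
frame, which prevents drift but leaves high-frequency frame-to-frame jitter.
This filter suppresses that jitter using the video itself: short LK-RSTC
tracklets are anchored at the noisy per-frame estimates at both ends of a
sliding window, and — here is the "transposed" part — each frame's final
position is the average over all overlapping tracklets' estimates at that
frame, i.e. averaging across windows rather than across time within one
window.  Because each tracklet follows the actual image motion, averaging
cancels anchor jitter without smearing genuine fast tissue motion the way a
plain low-pass filter would.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lkrstc import LKConfig, Tracklet, rstc_interpolate
from .media_io import VideoClip
from .trajectory import Trajectory

__all__ = [
    "RSTCFilterConfig",
    "window_frames",
    "build_tracklets",
    "coverage_count",
    "filter_trajectories",
]


@dataclass(frozen=True)
class RSTCFilterConfig:
    """Filter parameters.

    window_seconds
        Sliding-window duration; 0.5 s is the operating default.  Longer
        windows average more tracklets but admit more LK drift per tracklet.
    stride
        Window start spacing in frames.  1 (every frame) is exact; larger
        strides trade accuracy for speed.
    steepness
        Logistic steepness of the forward/reverse fusion inside tracklets.
    lk
        Lucas-Kanade solver configuration.
    """

    window_seconds: float = 0.5
    stride: int = 1
    steepness: float = 10.0
    lk: LKConfig = field(default_factory=LKConfig)

    def __post_init__(self) -> None:
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


def window_frames(cfg: RSTCFilterConfig, fps: float) -> int:
    """Window length in frames: ``W = round(window_seconds * fps)``.

    A 0.6 s window on a 50 Hz video is 30 frames.  W < 3 has no interior
    frames and is rejected (use a longer window or higher frame rate).
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    w = int(round(cfg.window_seconds * fps))
    if w < 3:
        raise ValueError(
            f"window of {cfg.window_seconds} s at {fps} Hz is only {w} frame(s); "
            "a tracklet needs >= 3 frames — increase the window or frame rate"
        )
    return w


def _check_anchors(anchors: list[Trajectory], clip: VideoClip, w: int) -> tuple[int, int]:
    first = anchors[0].first_frame
    n = len(anchors[0])
    for traj in anchors[1:]:
        if traj.first_frame != first or len(traj) != n:
            raise ValueError("anchor trajectories must share one frame range")
    if n < w:
        raise ValueError(f"anchor length {n} is shorter than the window ({w} frames)")
    if first + n > clip.frame_count:
        raise ValueError("anchors extend beyond the clip")
    return first, n


def build_tracklets(
    clip: VideoClip, anchors: list[Trajectory], cfg: RSTCFilterConfig | None = None
) -> list[Tracklet]:
    """One LK-RSTC tracklet per window position.

    Window starts are ``s = 0, stride, 2*stride, ... <= T - W`` (relative to
    the anchors' first frame); each tracklet is pinned to the anchor
    positions at its two end frames.  Tracklets are mutually independent, so
    the result does not depend on evaluation order.
    """
    cfg = cfg or RSTCFilterConfig()
    w = window_frames(cfg, anchors[0].fps)
    first, n = _check_anchors(anchors, clip, w)

    anchor_stack = np.stack([t.positions for t in anchors], axis=1)  # (T, n_pts, 2)
    tracklets = []
    for s in range(0, n - w + 1, cfg.stride):
        a = first + s
        b = first + s + w - 1
        tracklets.append(
            rstc_interpolate(
                clip, a, b,
                start_anchor=anchor_stack[s],
                end_anchor=anchor_stack[s + w - 1],
                cfg=cfg.lk,
                steepness=cfg.steepness,
            )
        )
    return tracklets


def coverage_count(frame: int, length: int, window: int, stride: int = 1) -> int:
    """Number of tracklets whose *interior* covers ``frame``.

    A tracklet starting at s spans interior frames ``s+1 .. s+window-2``.
    Interior frames at stride 1 are covered by ``window - 2`` tracklets;
    frames 0 and T-1 are never interior (count 0).
    """
    if not 0 <= frame < length:
        raise ValueError(f"frame {frame} outside [0, {length})")
    count = 0
    for s in range(0, length - window + 1, stride):
        if s + 1 <= frame <= s + window - 2:
            count += 1
    return count


def filter_trajectories(
    clip: VideoClip, anchors: list[Trajectory], cfg: RSTCFilterConfig | None = None
) -> list[Trajectory]:
    """Apply the transposed sliding-window filter to anchor trajectories.

    Per frame the output is the arithmetic mean of all valid tracklet
    estimates covering that frame.  Frames with no valid covering estimate —
    always the first and last frame, others only when LK fails — pass the
    anchor value through unchanged.  Output trajectories mirror the anchors'
    frame range and metadata.
    """
    cfg = cfg or RSTCFilterConfig()
    w = window_frames(cfg, anchors[0].fps)
    first, n = _check_anchors(anchors, clip, w)
    tracklets = build_tracklets(clip, anchors, cfg)

    n_pts = len(anchors)
    sums = np.zeros((n, n_pts, 2))
    counts = np.zeros((n, n_pts))
    for tr in tracklets:
        rel = tr.intermediate_frames - first  # indices into the anchor range
        valid = tr.status  # (N, n_pts)
        contrib = np.where(valid[..., None], tr.fused, 0.0)
        np.add.at(sums, rel, contrib)
        np.add.at(counts, rel, valid.astype(float))

    anchor_stack = np.stack([t.positions for t in anchors], axis=1)
    covered = counts > 0
    mean = np.where(covered[..., None], sums / np.maximum(counts, 1)[..., None], anchor_stack)

    return [
        traj.with_positions(mean[:, i, :]) for i, traj in enumerate(anchors)
    ]
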