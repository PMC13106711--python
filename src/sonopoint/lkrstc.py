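"""Bidirectional pyramidal Lucas-Kanade with sigmoid fusion (LK-RSTC).

Given a point's position in two anchor frames, LK-RSTC estimates the point
at every intermediate frame by tracking it with pyramidal Lucas-Kanade
optical flow in both directions — forward from the start anchor and reverse
from the end anchor — and blending the two paths per intermediate frame with
a logistic weight that trusts the nearer anchor's path more:

    fused(i) = (1 - w_i) * forward(i) + w_i * reverse(i),
    w_i = logistic(k * (i / (N + 1) - 1/2)),   i = 1..N intermediate frames.

Because each LK path drifts little over short horizons, pinning both ends to
trusted anchors and fusing yields sub-pixel interior estimates whose error
does not accumulate across the window.

The Lucas-Kanade solver here is a standard translational pyramidal
implementation (Gaussian image pyramid, Newton iterations on the patch
around the point, coarse-to-fine refinement) built on
``scipy.ndimage.map_coordinates`` for sub-pixel sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .media_io import VideoClip

__all__ = [
    "LKConfig",
    "FusionWeights",
    "Tracklet",
    "propagate",
    "track_path",
    "fusion_weights",
    "rstc_interpolate",
]

#: minimum acceptable determinant of the patch structure tensor, scaled by
#: patch area; below this the aperture problem makes the flow unsolvable
_MIN_DET = 1e-6


@dataclass(frozen=True)
class LKConfig:
    """Lucas-Kanade solver parameters.

    patch_size
        Side of the square patch tracked around the point (odd, px).  21 px
        comfortably spans several speckle grains at typical B-mode pitch.
    pyramid_levels
        Number of pyramid levels (>= 1); level l operates at 1/2**l scale.
    max_iterations
        Newton iteration cap per pyramid level.
    epsilon
        Convergence threshold on the per-iteration position update (px).
    """

    patch_size: int = 21
    pyramid_levels: int = 3
    max_iterations: int = 30
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        if self.patch_size < 3 or self.patch_size % 2 == 0:
            raise ValueError(f"patch_size must be odd and >= 3, got {self.patch_size}")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class FusionWeights:
    """Sigmoid fusion weights over a window's interior frames.

    ``weights[i-1]`` multiplies the reverse path at intermediate frame i;
    the forward path gets ``1 - weights[i-1]``.  Weights are strictly
    increasing, lie in (0, 1) and are symmetric: w_i + w_{N+1-i} = 1.
    """

    n_intermediate: int
    steepness: float
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.shape != (self.n_intermediate,):
            raise ValueError("weights length must equal n_intermediate")
        if np.any(w <= 0) or np.any(w >= 1):
            raise ValueError("weights must lie strictly in (0, 1)")
        if np.any(np.diff(w) <= 0):
            raise ValueError("weights must be strictly increasing")


@dataclass
class Tracklet:
    """Fused forward/reverse LK estimates over one anchor window's interior.

    ``fused`` has shape (n_intermediate, n_points, 2) and covers absolute
    frames ``start_frame+1 .. end_frame-1``; the anchors themselves are not
    part of the fused output.  ``status`` flags per (frame, point) validity.
    """

    start_frame: int
    end_frame: int
    start_anchor: np.ndarray
    end_anchor: np.ndarray
    fused: np.ndarray
    status: np.ndarray

    @property
    def n_intermediate(self) -> int:
        return self.end_frame - self.start_frame - 1

    @property
    def intermediate_frames(self) -> np.ndarray:
        """Absolute frame indices the fused estimates cover."""
        return np.arange(self.start_frame + 1, self.end_frame)


# ---------------------------------------------------------------------------
# image pyramids
# ---------------------------------------------------------------------------

def _build_pyramid(frame: np.ndarray, levels: int) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Gaussian pyramid with per-level central-difference gradients.

    Returns a list of (image, d/dy, d/dx) float32 triples, finest first.
    """
    img = np.asarray(frame, dtype=np.float32)
    pyramid = []
    for level in range(levels):
        gy, gx = np.gradient(img)
        pyramid.append((img, gy.astype(np.float32), gx.astype(np.float32)))
        if level + 1 < levels:
            if min(img.shape) < 8:
                break  # image too small to halve again
            img = ndimage.gaussian_filter(img, sigma=1.0, mode="nearest")[::2, ::2]
    return pyramid


def _clip_pyramid(clip: VideoClip, frame_index: int, levels: int):
    """Per-clip memoised pyramid (frames are reused by many tracklets)."""
    cache = clip._pyramid_cache
    key = (frame_index, levels)
    hit = cache.get(key)
    if hit is None:
        if len(cache) > 4000:  # bound memory on very long videos
            cache.clear()
        hit = cache[key] = _build_pyramid(clip.frames[frame_index], levels)
    return hit


def _sample(arr: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(arr, [ys, xs], order=1, mode="nearest", prefilter=False)


def _lk_point(pyr_a, pyr_b, point: np.ndarray, cfg: LKConfig) -> tuple[np.ndarray, bool]:
    """Track one point from pyramid A to pyramid B; returns (position, ok)."""
    r = (cfg.patch_size - 1) // 2
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1].astype(np.float64)
    dx = dx.ravel()
    dy = dy.ravel()
    levels = min(len(pyr_a), len(pyr_b))

    g = np.zeros(2)  # displacement guess carried down the pyramid (x, y)
    ok = True
    for level in range(levels - 1, -1, -1):
        img_a, gy_a, gx_a = pyr_a[level]
        img_b = pyr_b[level][0]
        scale = 2.0**level
        p = point / scale

        tx = p[0] + dx
        ty = p[1] + dy
        T = _sample(img_a, tx, ty)
        Ix = _sample(gx_a, tx, ty)
        Iy = _sample(gy_a, tx, ty)

        gxx = float(Ix @ Ix)
        gxy = float(Ix @ Iy)
        gyy = float(Iy @ Iy)
        det = gxx * gyy - gxy * gxy
        if det < _MIN_DET * dx.size:
            ok = False
            break
        inv = np.array([[gyy, -gxy], [-gxy, gxx]]) / det

        v = np.zeros(2)
        for _ in range(cfg.max_iterations):
            qx = tx + g[0] + v[0]
            qy = ty + g[1] + v[1]
            diff = T - _sample(img_b, qx, qy)
            b = np.array([float(Ix @ diff), float(Iy @ diff)])
            step = inv @ b
            v += step
            if float(step @ step) < cfg.epsilon**2:
                break
        g = 2.0 * (g + v) if level > 0 else g + v

    result = point + g
    h, w = pyr_b[0][0].shape
    in_bounds = 0.0 <= result[0] <= w - 1 and 0.0 <= result[1] <= h - 1
    ok = ok and in_bounds and bool(np.all(np.isfinite(result)))
    return result, ok


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def propagate(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    points: np.ndarray,
    cfg: LKConfig | None = None,
    _pyr_a=None,
    _pyr_b=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Propagate points from ``frame_a`` to ``frame_b`` with pyramidal LK.

    Parameters
    ----------
    frame_a, frame_b
        Grayscale images of identical dimensions.
    points
        Array (n, 2) of (x, y) positions in ``frame_a``.
    cfg
        Solver configuration; defaults to :class:`LKConfig()`.

    Returns
    -------
    positions : (n, 2) float array of sub-pixel positions in ``frame_b``.
    status : (n,) bool array — False where the point started out of bounds,
        the patch gradient was degenerate, or the solution left the image.
    """
    cfg = cfg or LKConfig()
    if _pyr_a is None or _pyr_b is None:
        frame_a = np.asarray(frame_a)
        frame_b = np.asarray(frame_b)
        if frame_a.shape != frame_b.shape:
            raise ValueError(
                f"frame dimension mismatch: {frame_a.shape} vs {frame_b.shape}"
            )
        _pyr_a = _build_pyramid(frame_a, cfg.pyramid_levels)
        _pyr_b = _build_pyramid(frame_b, cfg.pyramid_levels)

    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    h, w = _pyr_a[0][0].shape
    out = np.empty_like(pts)
    status = np.empty(pts.shape[0], dtype=bool)
    for i, p in enumerate(pts):
        if not (0.0 <= p[0] <= w - 1 and 0.0 <= p[1] <= h - 1):
            out[i] = p
            status[i] = False
            continue
        out[i], status[i] = _lk_point(_pyr_a, _pyr_b, p, cfg)
    return out, status


def track_path(
    clip: VideoClip,
    start_frame: int,
    end_frame: int,
    start_points: np.ndarray,
    direction: str = "forward",
    cfg: LKConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Chain LK propagation frame-by-frame across ``[start_frame, end_frame]``.

    ``forward`` seeds at ``start_frame`` and steps ahead; ``reverse`` seeds
    the same ``start_points`` at ``end_frame`` and steps backward.  Output is
    indexed by absolute frame: arrays of shape (end-start+1, n_points, 2) and
    (end-start+1, n_points).  Once a point's status drops it stays invalid
    for the rest of the path (the last valid position is carried forward).
    """
    cfg = cfg or LKConfig()
    if not 0 <= start_frame < end_frame < clip.frame_count:
        raise ValueError(
            f"invalid frame range [{start_frame}, {end_frame}] for a "
            f"{clip.frame_count}-frame clip"
        )
    if direction not in ("forward", "reverse"):
        raise ValueError(f"direction must be 'forward' or 'reverse', got {direction!r}")

    pts = np.atleast_2d(np.asarray(start_points, dtype=np.float64))
    n_span = end_frame - start_frame + 1
    positions = np.empty((n_span, pts.shape[0], 2))
    status = np.ones((n_span, pts.shape[0]), dtype=bool)

    order = (
        range(start_frame, end_frame + 1)
        if direction == "forward"
        else range(end_frame, start_frame - 1, -1)
    )
    order = list(order)
    current = pts.copy()
    alive = np.ones(pts.shape[0], dtype=bool)
    positions[order[0] - start_frame] = current
    for prev, nxt in zip(order[:-1], order[1:]):
        pyr_prev = _clip_pyramid(clip, prev, cfg.pyramid_levels)
        pyr_next = _clip_pyramid(clip, nxt, cfg.pyramid_levels)
        new_pos, ok = propagate(None, None, current, cfg, _pyr_a=pyr_prev, _pyr_b=pyr_next)
        alive = alive & ok
        current = np.where(alive[:, None], new_pos, current)
        idx = nxt - start_frame
        positions[idx] = current
        status[idx] = alive
    return positions, status


def fusion_weights(n_intermediate: int, steepness: float = 10.0) -> FusionWeights:
    """Logistic fusion weights for ``n_intermediate`` interior frames.

    w_i = logistic(k * (i/(N+1) - 1/2)) for i = 1..N, which is symmetric
    about the window midpoint (w_i + w_{N+1-i} = 1) and strictly increasing:
    early frames trust the forward path, late frames the reverse path.
    """
    if n_intermediate < 1:
        raise ValueError("n_intermediate must be >= 1")
    if steepness <= 0:
        raise ValueError("steepness must be positive")
    i = np.arange(1, n_intermediate + 1, dtype=np.float64)
    z = steepness * (i / (n_intermediate + 1) - 0.5)
    w = 1.0 / (1.0 + np.exp(-z))
    return FusionWeights(n_intermediate=n_intermediate, steepness=steepness, weights=w)


def rstc_interpolate(
    clip: VideoClip,
    start_frame: int,
    end_frame: int,
    start_anchor: np.ndarray,
    end_anchor: np.ndarray,
    cfg: LKConfig | None = None,
    steepness: float = 10.0,
) -> Tracklet:
    """Compute one LK-RSTC tracklet between two anchor frames.

    The forward LK path seeds at ``start_anchor`` on ``start_frame``; the
    reverse path seeds exactly at ``end_anchor`` on ``end_frame`` and steps
    backward.  Each intermediate frame blends the two paths with the logistic
    weight from :func:`fusion_weights`.  Where exactly one path is invalid
    the valid path's estimate is used; where both are invalid the status
    flag drops and the blend of the carried positions is reported.
    """
    cfg = cfg or LKConfig()
    if end_frame < start_frame + 2:
        raise ValueError(
            f"window [{start_frame}, {end_frame}] has no intermediate frames; "
            "need end_frame >= start_frame + 2"
        )
    start_anchor = np.atleast_2d(np.asarray(start_anchor, dtype=np.float64))
    end_anchor = np.atleast_2d(np.asarray(end_anchor, dtype=np.float64))
    if start_anchor.shape != end_anchor.shape:
        raise ValueError("start and end anchors must have matching shapes")

    fwd_pos, fwd_ok = track_path(clip, start_frame, end_frame, start_anchor, "forward", cfg)
    rev_pos, rev_ok = track_path(clip, start_frame, end_frame, end_anchor, "reverse", cfg)

    n_inter = end_frame - start_frame - 1
    w = fusion_weights(n_inter, steepness).weights  # (N,)
    interior = slice(1, n_inter + 1)
    f = fwd_pos[interior]  # (N, n_pts, 2)
    r = rev_pos[interior]
    fo = fwd_ok[interior]  # (N, n_pts)
    ro = rev_ok[interior]

    wcol = w[:, None, None]
    fused = (1.0 - wcol) * f + wcol * r
    only_f = fo & ~ro
    only_r = ro & ~fo
    fused[only_f] = f[only_f]
    fused[only_r] = r[only_r]
    status = fo | ro
    return Tracklet(
        start_frame=start_frame,
        end_frame=end_frame,
        start_anchor=start_anchor,
        end_anchor=end_anchor,
        fused=fused,
        status=status,
    )
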