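"""Synthetic speckle phantom: videos with exact ground-truth motion.

B-mode ultrasound frames show a granular interference texture ("speckle")
that is both noise and the very signature trackers lock onto.  This module
synthesises speckle-like textures, animates them under smooth parametric
motion models (translation, sinusoidal oscillation, shear), and returns the
closed-form ground-truth trajectories alongside the rendered frames — the
test bed standing in for real ultrasound data.

A companion simulator produces "noisy anchors": ground truth corrupted by
i.i.d. Gaussian jitter and optional slow linear drift, emulating the output
of per-frame CNN keypoint detectors.

Ground truth is always evaluated from the motion model's closed form, never
re-estimated from the rendered pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .media_io import VideoClip
from .trajectory import Trajectory

__all__ = [
    "MotionModel",
    "PhantomScene",
    "make_texture",
    "render_scene",
    "simulate_anchor_noise",
    "make_scene",
]

#: default scene geometry: 128x256 px at 50 Hz mirrors common B-mode captures
DEFAULT_HEIGHT = 128
DEFAULT_WIDTH = 256
DEFAULT_FPS = 50.0


@dataclass(frozen=True)
class MotionModel:
    """Parametric in-plane motion.

    kind:
        ``static`` — no motion.
        ``translation`` — constant velocity ``(vx, vy)`` px/frame.
        ``sinusoid`` — displacement ``amplitude * sin(2*pi*frequency*t)``
        along ``axis`` (t in seconds; frequency in Hz, below Nyquist).
        ``shear`` — horizontal displacement growing linearly with distance
        from the image vertical centre: ``dx = shear_rate * frame * (y - cy)``.
    """

    kind: str = "static"
    velocity: tuple[float, float] = (0.0, 0.0)
    amplitude: float = 0.0
    frequency: float = 1.0
    axis: str = "x"
    shear_rate: float = 0.0
    fps: float = DEFAULT_FPS
    center_y: float = DEFAULT_HEIGHT / 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("static", "translation", "sinusoid", "shear"):
            raise ValueError(f"unknown motion kind {self.kind!r}")
        if self.kind == "sinusoid":
            if self.frequency >= self.fps / 2:
                raise ValueError(
                    f"frequency {self.frequency} Hz violates Nyquist at fps={self.fps}"
                )
            if self.amplitude < 0:
                raise ValueError("amplitude must be >= 0")
        if self.axis not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")

    def displacement(self, frame: int, y: np.ndarray | float = 0.0) -> np.ndarray:
        """Closed-form displacement (dx, dy) at an integer frame index.

        For the shear model the displacement depends on y; the other models
        are spatially uniform.  Returns an array broadcastable against y.
        """
        if self.kind == "static":
            dx, dy = 0.0, 0.0
        elif self.kind == "translation":
            dx, dy = self.velocity[0] * frame, self.velocity[1] * frame
        elif self.kind == "sinusoid":
            d = self.amplitude * np.sin(2 * np.pi * self.frequency * frame / self.fps)
            dx, dy = (d, 0.0) if self.axis == "x" else (0.0, d)
        else:  # shear
            dx = self.shear_rate * frame * (np.asarray(y, dtype=float) - self.center_y)
            dy = 0.0
        return np.stack(np.broadcast_arrays(np.asarray(dx, float), np.asarray(dy, float)), axis=-1)

    def truth_positions(self, point: np.ndarray, n_frames: int) -> np.ndarray:
        """Exact trajectory of a material point over ``n_frames`` frames."""
        point = np.asarray(point, dtype=np.float64)
        out = np.empty((n_frames, 2))
        for t in range(n_frames):
            out[t] = point + self.displacement(t, y=point[1]).reshape(2)
        return out


@dataclass
class PhantomScene:
    """A rendered phantom clip plus its exact ground truth."""

    clip: VideoClip
    motion: MotionModel
    truth: list[Trajectory] = field(default_factory=list)
    seed: int = 0


def make_texture(seed: int, height: int = DEFAULT_HEIGHT, width: int = DEFAULT_WIDTH,
                 grain: float = 2.0) -> np.ndarray:
    """Synthesise an 8-bit speckle-like texture.

    Seeded white Gaussian noise is band-limited by a Gaussian blur at the
    grain scale and contrast-stretched over +/-3 sigma of its own
    distribution, yielding mid-gray images (mean ~128, std ~40) with a
    granular correlation length of roughly ``grain`` pixels.
    """
    if grain < 1:
        raise ValueError("grain must be >= 1 px")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((height, width))
    smooth = ndimage.gaussian_filter(noise, sigma=grain / 2.0, mode="wrap")
    mu, sigma = smooth.mean(), smooth.std()
    stretched = (smooth - mu) / (6.0 * sigma) + 0.5  # +/-3 sigma -> [0, 1]
    return np.clip(np.rint(stretched * 255.0), 0, 255).astype(np.uint8)


def render_scene(
    texture: np.ndarray,
    motion: MotionModel,
    n_frames: int,
    track_points: np.ndarray,
    seed: int = 0,
    pixel_noise_sigma: float = 0.0,
    fps: float | None = None,
) -> PhantomScene:
    """Animate a texture under a motion model and return scene + exact truth.

    Each frame resamples the texture with a bicubic warp: frame ``t`` pixel
    ``(x, y)`` takes the texture value at ``(x, y) - displacement(t)``
    (material points move *with* the displacement).  Bicubic interpolation
    is used because bilinear resampling blurs speckle enough to bias LK at
    sub-pixel shifts.  Optional additive Gaussian pixel noise is seeded.

    Raises if any tracked point would leave the image under the motion.
    """
    texture = np.asarray(texture)
    if texture.ndim != 2:
        raise ValueError("texture must be 2-D grayscale")
    h, w = texture.shape
    use_fps = fps if fps is not None else motion.fps
    track_points = np.atleast_2d(np.asarray(track_points, dtype=np.float64))

    # verify no tracked point exits the frame at any time
    for pi, pt in enumerate(track_points):
        pos = motion.truth_positions(pt, n_frames)
        bad = np.where(
            (pos[:, 0] < 0) | (pos[:, 0] > w - 1) | (pos[:, 1] < 0) | (pos[:, 1] > h - 1)
        )[0]
        if bad.size:
            raise ValueError(
                f"track point {pi} exits the frame at frame {int(bad[0])} "
                f"(position {pos[bad[0]]})"
            )

    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    for t in range(n_frames):
        disp = motion.displacement(t, y=yy)
        if disp.shape == (2,):
            dx = np.full_like(xx, disp[0])
            dy = np.full_like(yy, disp[1])
        else:
            dx, dy = disp[..., 0], disp[..., 1]
        src_rows = yy - dy
        src_cols = xx - dx
        img = ndimage.map_coordinates(
            texture.astype(np.float64), [src_rows, src_cols], order=3, mode="reflect"
        )
        if pixel_noise_sigma > 0:
            img = img + rng.normal(0.0, pixel_noise_sigma, img.shape)
        frames[t] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    clip = VideoClip(frames, fps=use_fps)
    truth = [
        Trajectory(label_id=i, positions=motion.truth_positions(pt, n_frames), fps=use_fps)
        for i, pt in enumerate(track_points)
    ]
    return PhantomScene(clip=clip, motion=motion, truth=truth, seed=seed)


def simulate_anchor_noise(
    truth: list[Trajectory],
    sigma: float = 2.0,
    drift_rate: float = 0.0,
    seed: int = 0,
) -> list[Trajectory]:
    """Corrupt ground-truth trajectories into jittery per-frame anchors.

    Emulates CNN keypoint output: independent Gaussian position noise of
    ``sigma`` px per frame and axis, plus optional slow drift accumulating
    at ``drift_rate`` px/frame along a seeded random fixed direction.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[Trajectory] = []
    for traj in truth:
        n = len(traj)
        noise = rng.normal(0.0, sigma, (n, 2)) if sigma > 0 else np.zeros((n, 2))
        drift = np.zeros((n, 2))
        if drift_rate != 0.0:
            angle = rng.uniform(0, 2 * np.pi)
            direction = np.array([np.cos(angle), np.sin(angle)])
            drift = np.outer(np.arange(n) * drift_rate, direction)
        out.append(traj.with_positions(traj.positions + noise + drift))
    return out


def make_scene(
    kind: str = "sinusoid",
    *,
    seed: int = 0,
    n_frames: int = 500,
    height: int = DEFAULT_HEIGHT,
    width: int = DEFAULT_WIDTH,
    fps: float = DEFAULT_FPS,
    amplitude: float = 4.0,
    frequency: float = 3.0,
    axis: str = "x",
    velocity: tuple[float, float] = (0.5, 0.0),
    shear_rate: float = 0.001,
    track_points: np.ndarray | None = None,
    grain: float = 2.0,
    pixel_noise_sigma: float = 0.0,
) -> PhantomScene:
    """Convenience front end: texture + motion model + rendering in one call.

    Defaults mirror the study conditions the package is validated under:
    128x256 px, 50 Hz, 500 frames, 3 Hz / 4 px sinusoid.
    """
    motion = MotionModel(
        kind=kind,
        velocity=velocity,
        amplitude=amplitude,
        frequency=frequency,
        axis=axis,
        shear_rate=shear_rate,
        fps=fps,
        center_y=height / 2.0,
    )
    if track_points is None:
        track_points = np.array(
            [[width * 0.5, height * 0.5], [width * 0.3, height * 0.4], [width * 0.7, height * 0.6]]
        )
    texture = make_texture(seed, height, width, grain=grain)
    return render_scene(
        texture, motion, n_frames, track_points,
        seed=seed + 1, pixel_noise_sigma=pixel_noise_sigma, fps=fps,
    )
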