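"""Grayscale video loading and persistence with frame-accurate random access.

This is the only module that touches containers/codecs.  The preferred
interchange format is a lossless frame stack (multipage TIFF or an NPZ array
archive) because compressed video codecs do not round-trip bit-exactly.
Compressed MP4/AVI containers are read-only and require an imageio plugin
capable of decoding them.

Conventions used throughout the package:

* frames are 8-bit grayscale arrays of shape (height, width);
* frame indexing is 0-based with half-open ranges ``[start, stop)``;
* image coordinates are ``(x, y)`` with x rightward along columns, y downward
  along rows, origin at the centre of the top-left pixel; sub-pixel positions
  are floats.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = ["VideoClip", "load_video", "save_video"]

#: file suffixes treated as lossless frame stacks
_STACK_SUFFIXES = (".tif", ".tiff", ".npz")


@dataclass
class VideoClip:
    """An in-memory grayscale video.

    Parameters
    ----------
    frames
        Array of shape ``(frame_count, height, width)``, dtype uint8.
    fps
        Frame rate in Hz.  Must be positive.
    pixel_pitch
        Physical pixel size in micrometres per pixel, if known.  Typical
        B-mode ultrasound is on the order of 75 um/px.
    """

    frames: np.ndarray
    fps: float = 50.0
    pixel_pitch: float | None = None
    _pyramid_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (frame_count, height, width); got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("empty video: frame_count must be >= 1")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.frames.dtype != np.uint8:
            self.frames = _to_uint8(self.frames)

    @property
    def frame_count(self) -> int:
        return int(self.frames.shape[0])

    @property
    def height(self) -> int:
        return int(self.frames.shape[1])

    @property
    def width(self) -> int:
        return int(self.frames.shape[2])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape  # type: ignore[return-value]

    @property
    def duration(self) -> float:
        """Clip duration in seconds."""
        return self.frame_count / self.fps

    def frame(self, i: int) -> np.ndarray:
        """Frame ``i`` (0-based).  Deterministic and repeatable."""
        if not 0 <= i < self.frame_count:
            raise IndexError(f"frame {i} out of range [0, {self.frame_count})")
        return self.frames[i]

    def __len__(self) -> int:
        return self.frame_count

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frame(i)

    def time_reversed(self) -> "VideoClip":
        """A copy with frames in reverse temporal order."""
        return VideoClip(self.frames[::-1].copy(), fps=self.fps, pixel_pitch=self.pixel_pitch)


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    """Convert an arbitrary numeric image stack to 8-bit by clipping."""
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    return np.clip(arr, 0, 255).astype(np.uint8)


def _luminance(frames: np.ndarray) -> np.ndarray:
    """Rec.601 luma conversion for (n, h, w, 3|4) colour stacks."""
    rgb = frames[..., :3].astype(np.float64)
    y = rgb @ np.array([0.299, 0.587, 0.114])
    return _to_uint8(y)


def load_video(path: str | os.PathLike, as_gray: bool = True, fps: float | None = None) -> VideoClip:
    """Load a video from disk.

    Supports lossless frame stacks (multipage ``.tif``/``.tiff``, ``.npz``
    archives written by :func:`save_video`) and, when an imageio codec plugin
    is available, compressed containers such as MP4/AVI.

    Parameters
    ----------
    path
        File to read.
    as_gray
        Convert colour input to luminance.  Grayscale input passes through.
    fps
        Override the frame rate recorded in (or absent from) the container.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"video file not found: {path}")

    suffix = os.path.splitext(path)[1].lower()
    meta_fps: float | None = None
    pixel_pitch: float | None = None

    if suffix == ".npz":
        with np.load(path) as archive:
            if "frames" not in archive:
                raise IOError(f"not a frame-stack archive (no 'frames' array): {path}")
            frames = archive["frames"]
            if "fps" in archive:
                meta_fps = float(archive["fps"])
            if "pixel_pitch" in archive and np.isfinite(archive["pixel_pitch"]):
                pixel_pitch = float(archive["pixel_pitch"])
    elif suffix in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            meta_fps = _tiff_fps(tf)
    else:
        frames, meta_fps = _load_via_imageio(path)

    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4:
        if as_gray:
            frames = _luminance(frames)
        else:
            raise ValueError(
                f"colour video loaded without as_gray: {path} has shape {frames.shape}"
            )
    if frames.ndim != 3:
        raise IOError(f"cannot interpret {path} as a frame stack: shape {frames.shape}")
    if frames.shape[0] == 0:
        raise IOError(f"empty video: {path} contains zero frames")

    clip_fps = fps if fps is not None else (meta_fps if meta_fps else 50.0)
    return VideoClip(frames, fps=clip_fps, pixel_pitch=pixel_pitch)


def _tiff_fps(tf) -> float | None:
    desc = tf.pages[0].tags.get("ImageDescription")
    if desc is not None and "fps=" in str(desc.value):
        try:
            return float(str(desc.value).split("fps=")[1].split()[0])
        except (ValueError, IndexError):
            return None
    return None


def _load_via_imageio(path: str) -> tuple[np.ndarray, float | None]:
    try:
        import imageio.v3 as iio

        frames = iio.imread(path, index=None)
        meta_fps = None
        try:
            meta = iio.immeta(path)
            meta_fps = float(meta["fps"]) if "fps" in meta else None
        except Exception:
            pass
        return np.asarray(frames), meta_fps
    except Exception as exc:  # plugin missing or undecodable container
        raise IOError(f"cannot decode video {path}: {exc}") from exc


def save_video(clip: VideoClip, path: str | os.PathLike, lossless: bool = True) -> str:
    """Persist a clip to disk.

    In lossless mode (``.npz`` or multipage ``.tif``) a subsequent
    :func:`load_video` reproduces the frames bitwise and preserves fps.
    Other suffixes are handed to imageio and only guarantee geometry,
    frame count and fps metadata where the container supports it.
    """
    path = os.fspath(path)
    suffix = os.path.splitext(path)[1].lower()

    if lossless and suffix not in _STACK_SUFFIXES:
        raise ValueError(
            f"lossless save requires a frame-stack suffix {_STACK_SUFFIXES}, got '{suffix}'"
        )

    if suffix == ".npz":
        np.savez_compressed(
            path,
            frames=clip.frames,
            fps=np.float64(clip.fps),
            pixel_pitch=np.float64(clip.pixel_pitch if clip.pixel_pitch is not None else np.nan),
        )
    elif suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, clip.frames, description=f"fps={clip.fps}")
    else:
        import imageio.v3 as iio

        iio.imwrite(path, clip.frames, fps=clip.fps)
    return path
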