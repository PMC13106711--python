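"""Per-point trajectories: contiguous sub-pixel position time series."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """A gap-free time series of 2-D positions for one tracked point.

    Parameters
    ----------
    label_id
        Numeric label of the tracked point.
    positions
        Array of shape ``(n_frames, 2)`` holding ``(x, y)`` pixel positions
        (floats, sub-pixel).  Must be finite.
    fps
        Frame rate in Hz.
    first_frame
        Absolute frame index of ``positions[0]``.
    pixel_pitch
        Micrometres per pixel, if known.
    """

    label_id: int
    positions: np.ndarray
    fps: float = 50.0
    first_frame: int = 0
    pixel_pitch: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError(f"positions must be (n, 2); got {self.positions.shape}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("trajectory positions must be finite")
        if self.first_frame < 0:
            raise ValueError("first_frame must be >= 0")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return int(self.positions.shape[0])

    @property
    def n_frames(self) -> int:
        return len(self)

    @property
    def last_frame(self) -> int:
        """Absolute index of the final frame (inclusive)."""
        return self.first_frame + len(self) - 1

    @property
    def frames(self) -> np.ndarray:
        """Absolute frame indices covered by this trajectory."""
        return np.arange(self.first_frame, self.first_frame + len(self))

    @property
    def times(self) -> np.ndarray:
        """Timestamps in seconds relative to frame 0 of the video."""
        return self.frames / self.fps

    @property
    def x(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.positions[:, 1]

    def at(self, frame: int) -> np.ndarray:
        """Position at an absolute frame index."""
        if not self.first_frame <= frame <= self.last_frame:
            raise IndexError(
                f"frame {frame} outside trajectory range "
                f"[{self.first_frame}, {self.last_frame}]"
            )
        return self.positions[frame - self.first_frame]

    def with_positions(self, positions: np.ndarray) -> "Trajectory":
        """Copy carrying new positions but identical metadata."""
        return Trajectory(
            label_id=self.label_id,
            positions=positions,
            fps=self.fps,
            first_frame=self.first_frame,
            pixel_pitch=self.pixel_pitch,
        )

    def same_range(self, other: "Trajectory") -> bool:
        return self.first_frame == other.first_frame and len(self) == len(other)
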