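"""Core calibrated containers shared by all analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageStack:
    """A calibrated fluorescence movie.

    Parameters
    ----------
    data : ndarray, shape (n_frames, rows, cols)
        Pixel intensities in camera counts.
    pixel_size : float
        Lateral pixel size in micrometres.
    frame_interval : float
        Time between frames in seconds.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("data must be a (n_frames, rows, cols) array")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ImageStack):
            return NotImplemented
        return (
            self.pixel_size == other.pixel_size
            and self.frame_interval == other.frame_interval
            and self.data.shape == other.data.shape
            and self.data.dtype == other.data.dtype
            and bool(np.array_equal(self.data, other.data))
        )


@dataclass
class IntensityTrace:
    """Per-frame intensity of one tracked assembly (or one fluorophore).

    ``values[i]`` is the 6-px-disc mean intensity at frame
    ``origin_frame - back_extended_frames + i``.  ``back_extended_frames``
    counts frames prepended *before* the first detected frame so that the
    pre-assembly baseline is part of the trace.
    """

    values: np.ndarray
    frame_interval: float
    origin_frame: int = 0
    back_extended_frames: int = 0
    traj_id: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.back_extended_frames < 0:
            raise ValueError("back_extended_frames must be >= 0")

    def __len__(self) -> int:
        return self.values.size

    @property
    def frames(self) -> np.ndarray:
        """Absolute frame index of every trace sample."""
        start = self.origin_frame - self.back_extended_frames
        return np.arange(start, start + len(self))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntensityTrace):
            return NotImplemented
        return (
            self.frame_interval == other.frame_interval
            and self.origin_frame == other.origin_frame
            and self.back_extended_frames == other.back_extended_frames
            and bool(np.array_equal(self.values, other.values))
        )
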