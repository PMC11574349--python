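"""Image stack container used by every raster-processing stage.

A stack is a ``T x Y x X`` array of non-negative intensities in arbitrary
units, carrying the two pieces of acquisition metadata the analyses need:
the pixel size in micrometres and the frame interval in seconds.  Stacks
are stored on disk as multi-page grayscale TIFF (16-bit) with a YAML
sidecar for the metadata, since plain TIFF tags are not reliable across
writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageStack:
    """Time-lapse (or single-frame) grayscale image stack.

    Parameters
    ----------
    data : ndarray, shape (T, Y, X)
        Non-negative intensities in arbitrary units.  Quantized to 16 bit
        on write; in memory float or integer are both accepted.
    pixel_size_um : float
        Lateral pixel size, micrometres per pixel.
    frame_interval_s : float
        Time between consecutive frames, seconds.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[np.newaxis]
        if self.data.ndim != 3:
            raise ValueError(f"stack must be T x Y x X, got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("stack must contain at least one frame")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if np.any(np.asarray(self.data, dtype=float) < 0):
            raise ValueError("stack intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def times_min(self) -> np.ndarray:
        """Frame times in minutes, starting at 0 for frame 0."""
        return np.arange(self.n_frames) * self.frame_interval_s / 60.0

    def quantized(self) -> np.ndarray:
        """Data rounded and clipped to the 16-bit range, as uint16."""
        return np.clip(np.round(self.data), 0, 65535).astype(np.uint16)


@dataclass
class ChannelStack:
    """Multi-channel single-frame image (fixed-embryo acquisitions).

    ``channels[0]`` is the nuclear channel; subsequent entries are
    expression channels.  Each channel is a Y x X array.
    """

    channels: list = field(default_factory=list)
    pixel_size_um: float = 1.0
    channel_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.channels = [np.asarray(c) for c in self.channels]
        if not self.channels:
            raise ValueError("at least one channel required")
        shapes = {c.shape for c in self.channels}
        if len(shapes) != 1:
            raise ValueError("channels must share a shape")
        if not self.channel_names:
            self.channel_names = ["nuclear"] + [
                f"expr{i}" for i in range(1, len(self.channels))
            ]
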