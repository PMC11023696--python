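"""Core data containers shared across the pipeline.

Two containers carry almost all data: :class:`TraceSeries` for uniformly
sampled time series (fluorescence, eye angle, stimulus position) and
:class:`ImageStack` for single-channel time-lapse image stacks.  Both are
thin, immutable-by-convention wrappers around numpy arrays that keep the
sampling metadata (rate / pixel size) attached to the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class TraceSeries:
    """A uniformly sampled time series.

    Parameters
    ----------
    values : ndarray, shape (n,)
        Sample values.  Units depend on the channel (arbitrary fluorescence
        units, percent modulation, or degrees of visual angle).
    rate : float
        Sampling rate in Hz.  Must be positive.
    channel : str
        Free-form channel label (e.g. ``"texasred"``, ``"eye"``).
    t0 : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    rate: float
    channel: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TraceSeries values must be 1-D")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Total span covered by the samples, in seconds (n / rate)."""
        return self.n / self.rate

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def with_values(self, values: np.ndarray, channel: str | None = None) -> "TraceSeries":
        """Copy of this series with new values (same rate/origin)."""
        out = replace(self, values=np.asarray(values, dtype=float))
        if channel is not None:
            out.channel = channel
        return out

    def slice_time(self, start: float, stop: float) -> "TraceSeries":
        """Sub-series covering [start, stop) in seconds relative to t0."""
        i0 = int(round(start * self.rate))
        i1 = int(round(stop * self.rate))
        if not (0 <= i0 < i1 <= self.n):
            raise ValueError(f"window [{start}, {stop}) s outside trace of {self.duration} s")
        return TraceSeries(self.values[i0:i1], self.rate, self.channel,
                           self.t0 + i0 / self.rate)


@dataclass
class ImageStack:
    """A frames x Y x X single-channel fluorescence stack.

    Intensities are in arbitrary fluorescence units.  After background
    subtraction values may be slightly negative (noise); downstream code
    must tolerate that.
    """

    data: np.ndarray
    pixel_size: float  # µm per pixel
    frame_rate: float  # Hz
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ImageStack data must be (frames, Y, X)")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class ROI:
    """Rectangular pixel region: rows [y0, y1) x columns [x0, x1)."""

    y0: int
    y1: int
    x0: int
    x1: int

    def __post_init__(self) -> None:
        if self.y1 <= self.y0 or self.x1 <= self.x0:
            raise ValueError("ROI must have positive extent")

    def check_inside(self, frame_shape: tuple) -> None:
        ny, nx = frame_shape
        if self.y0 < 0 or self.x0 < 0 or self.y1 > ny or self.x1 > nx:
            raise ValueError(f"ROI {self} outside frame of shape {frame_shape}")

    def mean_of(self, frame: np.ndarray) -> float:
        return float(frame[self.y0:self.y1, self.x0:self.x1].mean())
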