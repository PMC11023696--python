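"""Detection and summary statistics of spontaneous vasodilation events.

Works on a baseline-normalized trace (percent dilation, ~0 at rest).
Contiguous supra-threshold excursions become candidate events; overlapping
events are split at local minima between supra-threshold peaks.  The three
classic summary statistics — inter-event interval (peak to peak), peak
amplitude, and unit dilation time (full width at half of the peak
amplitude) — are accumulated per session, turned into cumulative relative
frequency curves, and averaged across sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import TraceSeries

__all__ = ["DilationEvent", "EventSummary", "detect_events",
           "auto_threshold", "summarize_events"]


@dataclass
class DilationEvent:
    onset_time: float  # s, rising threshold crossing before the peak
    peak_time: float  # s
    peak_amplitude: float  # % above baseline
    half_width: float  # s, full width at half of peak amplitude

    def __post_init__(self) -> None:
        if not self.peak_amplitude > 0:
            raise ValueError("peak_amplitude must be positive")
        if not self.half_width > 0:
            raise ValueError("half_width must be positive")
        if self.onset_time > self.peak_time:
            raise ValueError("onset must not follow the peak")


@dataclass
class EventSummary:
    """Per-session statistics plus averaged cumulative frequency curves."""

    inter_event_intervals: list = field(default_factory=list)  # per session
    peak_amplitudes: list = field(default_factory=list)
    half_widths: list = field(default_factory=list)
    cumulative: dict = field(default_factory=dict)  # stat -> (grid, mean curve)

    @property
    def all_intervals(self) -> np.ndarray:
        return np.concatenate([np.asarray(v) for v in self.inter_event_intervals]) \
            if self.inter_event_intervals else np.empty(0)

    @property
    def all_amplitudes(self) -> np.ndarray:
        return np.concatenate([np.asarray(v) for v in self.peak_amplitudes]) \
            if self.peak_amplitudes else np.empty(0)

    @property
    def all_half_widths(self) -> np.ndarray:
        return np.concatenate([np.asarray(v) for v in self.half_widths]) \
            if self.half_widths else np.empty(0)


def auto_threshold(values: np.ndarray, k: float = 3.0) -> float:
    """k x robust noise SD of the trace.

    The noise scale is 1.4826 * MAD of the successive differences divided
    by sqrt(2): unlike the plain MAD of the trace, this estimate is not
    inflated by the dilation transients themselves, which occupy a large
    fraction of a typical session.
    """
    d = np.diff(values)
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(k * 1.4826 * mad / np.sqrt(2.0))


def _boxcar(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return y
    k = np.ones(width) / width
    half = width // 2
    pad = np.pad(y, half, mode="edge")
    return np.convolve(pad, k, mode="same")[half:half + y.size]


def _half_crossing_left(t: np.ndarray, y: np.ndarray, i_peak: int,
                        level: float, i_stop: int) -> float | None:
    """Interpolated time where y last rose through ``level`` left of the
    peak, searching no further back than ``i_stop``."""
    i = i_peak
    while i > i_stop:
        if y[i - 1] < level <= y[i]:
            f = (level - y[i - 1]) / (y[i] - y[i - 1])
            return float(t[i - 1] + f * (t[i] - t[i - 1]))
        i -= 1
    return None


def _half_crossing_right(t: np.ndarray, y: np.ndarray, i_peak: int,
                         level: float, i_stop: int) -> float | None:
    i = i_peak
    while i < i_stop:
        if y[i] >= level > y[i + 1]:
            f = (y[i] - level) / (y[i] - y[i + 1])
            return float(t[i] + f * (t[i + 1] - t[i]))
        i += 1
    return None


def detect_events(trace: TraceSeries,
                  threshold: float | str = "auto:3",
                  smooth_samples: int = 3) -> list[DilationEvent]:
    """Detect dilation events on a baseline-normalized percent trace.

    ``threshold`` is a percent level, or ``"auto:k"`` for k x robust noise
    SD (default k = 3).  Each supra-threshold excursion yields one event
    per prominent local peak (overlapping events are split at the local
    minimum between supra-threshold peaks).  Peak amplitude is read from
    the raw trace; half-maximum crossings are located by linear
    interpolation on a short boxcar-smoothed copy (``smooth_samples``,
    default 3) so that sample noise on the slow decay flank does not
    trigger early crossings.  Events whose half-maximum crossings cannot
    be resolved inside the trace (or inside their own excursion, for
    overlaps) are discarded.
    """
    if trace.n == 0:
        raise ValueError("empty trace")
    y = trace.values
    t = trace.time
    baseline = np.median(y)
    if abs(baseline) > max(1.0, 0.1 * np.ptp(y)) and np.ptp(y) > 0:
        warnings.warn(f"trace baseline {baseline:.2f}% far from 0; "
                      "expected a baseline-normalized trace")
    if isinstance(threshold, str):
        if not threshold.startswith("auto"):
            raise ValueError(f"unrecognized threshold spec {threshold!r}")
        k = float(threshold.split(":")[1]) if ":" in threshold else 3.0
        thr = auto_threshold(y, k)
    else:
        thr = float(threshold)

    ys = _boxcar(y, smooth_samples)
    above = ys > thr
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = [0] if above[0] else []
    starts += list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[-1]:
        ends.append(y.size)

    events: list[DilationEvent] = []
    for j, (s, e) in enumerate(zip(starts, ends)):
        prev_end = ends[j - 1] if j > 0 else 0
        next_start = starts[j + 1] if j + 1 < len(starts) else y.size - 1
        seg = ys[s:e]
        # split multi-peak excursions at local minima between peaks;
        # the prominence floor keeps noise wiggles from splitting one event
        peaks, _ = signal.find_peaks(seg, prominence=thr)
        if peaks.size == 0:
            peaks = np.array([int(np.argmax(seg))])
        bounds = [s]
        for a, b in zip(peaks[:-1], peaks[1:]):
            bounds.append(s + a + int(np.argmin(seg[a:b + 1])))
        bounds.append(e)
        for i_pk, (b0, b1) in zip(peaks, zip(bounds[:-1], bounds[1:])):
            i_s = s + i_pk
            # raw-trace peak in the immediate neighborhood of the smoothed one
            lo = max(b0, i_s - smooth_samples)
            hi = min(b1, i_s + smooth_samples + 1)
            i_peak = lo + int(np.argmax(y[lo:hi]))
            amp = float(y[i_peak])
            if amp <= thr:
                continue
            half = amp / 2.0
            # search stops at the event's own bounds: the split point inside
            # a multi-peak excursion, or the neighboring excursion outside it
            i_left_stop = b0 if b0 > s else prev_end
            i_right_stop = b1 - 1 if b1 < e else next_start
            left = _half_crossing_left(t, ys, i_s, half, i_left_stop)
            right = _half_crossing_right(t, ys, i_s, half, i_right_stop)
            if left is None or right is None:
                continue  # crossing unresolved (trace edge or overlap)
            onset = _half_crossing_left(t, ys, i_s, thr, i_left_stop)
            events.append(DilationEvent(onset if onset is not None else left,
                                        float(t[i_peak]), amp, right - left))
    return events


def summarize_events(sessions: list[list[DilationEvent]],
                     grid_points: int = 200) -> EventSummary:
    """Summarize detected events across sessions.

    Inter-event intervals are successive peak-time differences within a
    session.  For each statistic a per-session cumulative relative
    frequency curve is evaluated on a common grid and averaged across
    sessions (sessions with fewer than 2 events contribute no intervals
    and are flagged by an empty interval list).
    """
    summary = EventSummary()
    for evs in sessions:
        pk = np.array([e.peak_time for e in evs])
        summary.inter_event_intervals.append(np.diff(pk) if pk.size >= 2
                                             else np.empty(0))
        summary.peak_amplitudes.append(np.array([e.peak_amplitude for e in evs]))
        summary.half_widths.append(np.array([e.half_width for e in evs]))

    for name, per_session in (
            ("interval", summary.inter_event_intervals),
            ("amplitude", summary.peak_amplitudes),
            ("half_width", summary.half_widths)):
        pooled = np.concatenate([np.asarray(v) for v in per_session]) \
            if per_session else np.empty(0)
        if pooled.size == 0:
            continue
        grid = np.linspace(0.0, float(pooled.max()), grid_points)
        curves = [np.searchsorted(np.sort(v), grid, side="right") / len(v)
                  for v in per_session if len(v) > 0]
        summary.cumulative[name] = (grid, np.mean(curves, axis=0))
    return summary
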