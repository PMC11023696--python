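"""Phase estimation between oscillatory channels and against the stimulus.

Two estimators are provided.  For channel pairs that mirror each other
(intravascular dye vs parenchymal shadow), the lag of the negative
cross-correlation peak near zero (delta-t) is converted to a phase by
``(delta_t / cycle) * 360 + 180`` degrees.  For stimulus-locked responses
(eye traces, fluorescence), the trace is cut into stimulus-cycle segments,
averaged, and fitted with a fixed-frequency sinusoid whose phase is read
against the stimulus.  Segments are optionally screened by the spectral
peak ratio (keep PR > 3) so only frequency-locked epochs enter the phase
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .core import TraceSeries
from .spectral import amplitude_spectrum, peak_ratio

__all__ = [
    "PhaseLagResult",
    "SegmentSet",
    "EntrainedSelection",
    "crosscorr_lag",
    "phase_from_lag",
    "segment_average",
    "sine_fit_phase",
    "select_entrained_segments",
]


@dataclass
class PhaseLagResult:
    delta_t: float  # s, lag of the negative cross-correlation peak
    cycle: float  # s, stimulus period
    phase: float  # deg in [0, 360)

    def __post_init__(self) -> None:
        if abs(self.delta_t) > self.cycle:
            raise ValueError("|delta_t| must not exceed the cycle")


@dataclass
class SegmentSet:
    """Cycle-aligned fixed-length segments of a trace plus their mean."""

    segments: np.ndarray  # (count, samples_per_cycle)
    cycle: float  # s
    rate: float  # Hz
    mean_segment: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mean_segment = self.segments.mean(axis=0)

    @property
    def count(self) -> int:
        return self.segments.shape[0]


@dataclass
class EntrainedSelection:
    """Analysis windows of a trace screened by the peak-ratio statistic."""

    windows: list  # kept windows, as TraceSeries
    kept: np.ndarray  # boolean per window
    prs: np.ndarray  # PR per window
    segment_len: float  # s

    @property
    def kept_fraction(self) -> float:
        return float(self.kept.mean()) if self.kept.size else 0.0


def crosscorr_lag(a: TraceSeries, b: TraceSeries, max_lag: float,
                  refine: bool = False) -> float | None:
    """Lag (s) of the most negative cross-correlation local minimum within
    ``[-max_lag, +max_lag]``; positive means ``b`` lags ``a``.

    Both traces are mean-subtracted and the correlation normalized to
    [-1, 1].  Only local minima strictly inside the window count, and a
    minimum must fall below ``-3/sqrt(n)`` — three times the correlation
    floor of independent white traces — to qualify as a negative peak, so
    a positively correlated pair whose in-range correlation merely wiggles
    around zero is excluded (returns None) rather than assigned a phase.
    Ties are broken toward the smallest |lag|.  With ``refine``, a
    parabola through the minimum and its neighbors gives a sub-sample lag.
    """
    if a.n != b.n:
        raise ValueError("traces must have equal length")
    if a.rate != b.rate:
        raise ValueError("traces must share a sampling rate")
    x = a.values - a.values.mean()
    y = b.values - b.values.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        return None
    c = _signal.correlate(y, x, mode="full") / denom
    lags = _signal.correlation_lags(y.size, x.size) / a.rate
    keep = np.abs(lags) <= max_lag + 1e-12
    c, lags = c[keep], lags[keep]

    floor = -3.0 / np.sqrt(a.n)
    interior = np.arange(1, c.size - 1)
    is_min = (c[interior] <= c[interior - 1]) & (c[interior] < c[interior + 1]) \
        & (c[interior] < floor)
    cand = interior[is_min]
    if cand.size == 0:
        return None
    order = np.lexsort((np.abs(lags[cand]), c[cand]))
    i = cand[order[0]]
    lag = lags[i]
    if refine:
        denom2 = c[i - 1] - 2.0 * c[i] + c[i + 1]
        if denom2 > 0:
            lag = lag + 0.5 * (c[i - 1] - c[i + 1]) / denom2 / a.rate
    return float(lag)


def phase_from_lag(delta_t: float, cycle: float) -> float:
    """Convert a mirror-pair lag to a phase: (delta_t/cycle)*360 + 180,
    wrapped to [0, 360)."""
    if cycle <= 0:
        raise ValueError("cycle must be positive")
    if abs(delta_t) > cycle:
        raise ValueError("|delta_t| must not exceed the cycle")
    return float(((delta_t / cycle) * 360.0 + 180.0) % 360.0)


def segment_average(trace: TraceSeries, cycle: float,
                    analysis_window: float | None = None) -> SegmentSet:
    """Cut the trace into cycle-length segments and average them.

    Segments start at stimulus-cycle boundaries from the beginning of the
    analysis window (default: the whole trace); a 300 s window at the 4 s
    cycle yields 75 segments.  The sampling rate and cycle must be
    commensurate (integer samples per cycle).
    """
    window = trace.duration if analysis_window is None else analysis_window
    if window > trace.duration + 1e-9:
        raise ValueError("analysis_window longer than the trace")
    n_per = cycle * trace.rate
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError(
            f"cycle ({cycle} s) must be an integer number of samples at {trace.rate} Hz")
    n_per = int(round(n_per))
    count = int(np.floor(window / cycle + 1e-9))
    if count < 1:
        raise ValueError("analysis window shorter than one cycle")
    seg = trace.values[:count * n_per].reshape(count, n_per)
    return SegmentSet(seg, cycle, trace.rate)


def sine_fit_phase(mean_segment: np.ndarray, cycle: float,
                   rate: float) -> tuple[float, float, float]:
    """Least-squares fit of ``A sin(2 pi t / cycle + phi) + c`` with the
    frequency fixed; linear in the sin/cos basis, solved in closed form.

    Returns (amplitude, phase_deg, offset); the phase is relative to a
    stimulus ``sin(2 pi t / cycle)`` starting at the segment start, in
    (-180, 180].  A response lagging the stimulus by L degrees fits
    phi = -L.  A zero-variance segment returns amplitude 0 and NaN phase.
    """
    y = np.asarray(mean_segment, dtype=float)
    t = np.arange(y.size) / rate
    w = 2.0 * np.pi / cycle
    if np.ptp(y) == 0:
        return 0.0, float("nan"), float(y.mean() if y.size else np.nan)
    design = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t)])
    (ps, pc, c), *_ = np.linalg.lstsq(design, y, rcond=None)
    amplitude = float(np.hypot(ps, pc))
    phase = float(np.rad2deg(np.arctan2(pc, ps)))
    return amplitude, phase, float(c)


def select_entrained_segments(trace: TraceSeries, pr_threshold: float = 3.0,
                              segment_len: float = 40.0, f0: float = 0.25,
                              band: tuple[float, float] = (0.1, 1.0),
                              ) -> EntrainedSelection:
    """Tile the trace into analysis windows and keep those whose peak
    ratio at ``f0`` exceeds ``pr_threshold``.

    The default 40 s window holds ten 0.25 Hz stimulus cycles and puts f0
    exactly on a frequency bin.  Kept windows feed the cross-correlation /
    phase estimators; an empty selection means no frequency-locked epoch
    was found.
    """
    win_n = int(round(segment_len * trace.rate))
    if win_n < 2 or win_n > trace.n:
        raise ValueError("segment_len must fit within the trace")
    n_win = trace.n // win_n
    prs = np.empty(n_win)
    windows = []
    for i in range(n_win):
        seg = trace.values[i * win_n:(i + 1) * win_n]
        sub = TraceSeries(seg - seg.mean(), trace.rate, trace.channel,
                          trace.t0 + i * win_n / trace.rate)
        prs[i] = peak_ratio(amplitude_spectrum(sub), f0, band).pr
        windows.append(sub)
    kept = prs > pr_threshold
    return EntrainedSelection([w for w, k in zip(windows, kept) if k],
                              kept, prs, segment_len)
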