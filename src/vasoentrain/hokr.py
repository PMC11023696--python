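"""Optokinetic-response (HOKR) eye-trace processing and gain analysis.

An eye-angle trace tracking a horizontally oscillating stripe pattern is
cleaned of saccades (inter-frame steps above 1 degree of visual angle),
bandpass filtered (100–500 mHz) to remove slow drift and offset, and its
oscillation amplitude read out per stimulus cycle as the difference of the
averaged per-cycle maxima and minima.  Across a spaced-training schedule,
amplitudes are normalized to the first test of the first session (relative
gain), and the gain can be correlated with the vasomotion entrainment
peak-ratio statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .core import TraceSeries

__all__ = [
    "SessionSchedule",
    "GainSeries",
    "detect_saccades",
    "remove_saccades",
    "bandpass_eye",
    "eye_amplitude",
    "relative_gain",
    "gain_pr_correlation",
]

# Test labels of the spaced-training schedule: early/late windows of four
# 15-min sessions on day 1 (1 h apart), then 2-min probe tests on days 2
# and 5 -> 10 tests in all.
DEFAULT_TEST_LABELS = (
    "day1_s1_early", "day1_s1_late", "day1_s2_early", "day1_s2_late",
    "day1_s3_early", "day1_s3_late", "day1_s4_early", "day1_s4_late",
    "day2", "day5",
)


@dataclass(frozen=True)
class SessionSchedule:
    """Spaced-training schedule.

    Defaults: four 15 min training sessions at 1 h intervals on day 1 and
    2 min tests on days 2 and 5; eye-movement analysis windows are the
    first and last 3 min of each training session (full 2 min for the probe
    tests), fluorescence windows the first and last 5 min.
    """

    test_labels: tuple = DEFAULT_TEST_LABELS
    training_duration: float = 900.0  # s
    eye_window: float = 180.0  # s
    fluor_window: float = 300.0  # s
    probe_duration: float = 120.0  # s

    @property
    def n_tests(self) -> int:
        return len(self.test_labels)


@dataclass
class GainSeries:
    """Per-test eye amplitudes and their relative gain (first test = 1)."""

    amplitudes: np.ndarray  # deg
    labels: tuple = ()
    relative_gain: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes[0] == 0:
            raise ValueError("first-test amplitude is zero; cannot normalize")
        self.relative_gain = self.amplitudes / self.amplitudes[0]


def detect_saccades(trace: TraceSeries,
                    step_threshold: float = 1.0) -> np.ndarray:
    """Indices of frames where the inter-frame step exceeds the threshold
    (the frame *before* each supra-threshold step)."""
    return np.flatnonzero(np.abs(np.diff(trace.values)) > step_threshold)


def remove_saccades(trace: TraceSeries, step_threshold: float = 1.0,
                    guard: int = 1, recovery_s: float = 0.5,
                    max_passes: int = 10) -> TraceSeries:
    """Remove saccadic steps and gap-fill by linear interpolation.

    Any inter-frame step larger than ``step_threshold`` degrees flags a
    saccade; the flagged samples, a ``guard`` of frames on each side, and
    a ``recovery_s`` post-saccadic window (the glissadic re-centering
    after the step, which would otherwise leak into the oscillation band)
    are replaced by linear interpolation so the sampling stays uniform —
    the filtering and FFT downstream require it.  Interpolation across a
    wide gap can itself leave a supra-threshold step, so detection repeats
    until no step remains; the operation is therefore idempotent.
    """
    y = trace.values.copy()
    n = y.size
    rec = int(round(recovery_s * trace.rate))
    for _ in range(max_passes):
        idx = np.flatnonzero(np.abs(np.diff(y)) > step_threshold)
        if idx.size == 0:
            break
        bad = np.zeros(n, dtype=bool)
        for i in idx:
            bad[max(0, i - guard):min(n, i + 2 + guard + rec)] = True
        good = ~bad
        if good.sum() < 2:
            break
        y[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(good), y[good])
    return trace.with_values(y)


def bandpass_eye(trace: TraceSeries, band: tuple[float, float] = (0.1, 0.5),
                 order: int = 4) -> TraceSeries:
    """Zero-phase Butterworth bandpass (default 100–500 mHz).

    Passes the 0.25 Hz tracking component essentially unattenuated while
    suppressing DC offset and slow drift by orders of magnitude.
    """
    lo, hi = band
    nyq = trace.rate / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} outside (0, Nyquist = {nyq} Hz)")
    if trace.duration < 3.0 / lo:
        raise ValueError("trace shorter than three periods of the band low edge")
    sos = signal.butter(order, band, btype="bandpass", fs=trace.rate,
                        output="sos")
    return trace.with_values(signal.sosfiltfilt(sos, trace.values))


def eye_amplitude(trace: TraceSeries, cycle: float,
                  window: tuple[float, float] | None = None) -> float:
    """Oscillation amplitude (deg): mean per-cycle maximum minus mean
    per-cycle minimum over the analysis window.

    Expects a saccade-removed, bandpassed trace.  The window is (start,
    stop) in seconds relative to the trace start; default is the whole
    trace.  One max and one min are located in each full stimulus cycle.
    """
    sub = trace if window is None else trace.slice_time(*window)
    n_per = cycle * sub.rate
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("cycle must be an integer number of samples")
    n_per = int(round(n_per))
    n_cycles = sub.n // n_per
    if n_cycles < 1:
        raise ValueError("window shorter than one stimulus cycle")
    seg = sub.values[:n_cycles * n_per].reshape(n_cycles, n_per)
    return float(seg.max(axis=1).mean() - seg.min(axis=1).mean())


def relative_gain(amplitudes, schedule: SessionSchedule | None = None) -> GainSeries:
    """Normalize per-test amplitudes to the first test of the first session."""
    schedule = schedule or SessionSchedule()
    amplitudes = np.asarray(amplitudes, dtype=float)
    labels = schedule.test_labels[:len(amplitudes)] \
        if len(amplitudes) <= schedule.n_tests else tuple(range(len(amplitudes)))
    return GainSeries(amplitudes, labels)


def gain_pr_correlation(gains: np.ndarray, prs: np.ndarray,
                        mode: str = "group-mean",
                        schedule: SessionSchedule | None = None,
                        ) -> tuple[float, float, int]:
    """Pearson correlation between HOKR relative gain and the peak ratio.

    ``gains`` and ``prs`` are (animals x tests) arrays on the same
    schedule.  ``group-mean`` averages across animals per test and
    correlates over tests.  ``per-animal-day5`` correlates, across
    animals, the day-5 gain normalized to the late window of training
    session 4 against the PR of that same late-session-4 window.
    Returns (r, p, n).
    """
    schedule = schedule or SessionSchedule()
    g = np.atleast_2d(np.asarray(gains, dtype=float))
    q = np.atleast_2d(np.asarray(prs, dtype=float))
    if g.shape != q.shape:
        raise ValueError("gains and prs must have matching shapes")
    if mode == "group-mean":
        x = g.mean(axis=0)
        y = q.mean(axis=0)
    elif mode == "per-animal-day5":
        labels = schedule.test_labels
        i5 = labels.index("day5")
        i4 = labels.index("day1_s4_late")
        x = g[:, i5] / g[:, i4]
        y = q[:, i4]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)
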