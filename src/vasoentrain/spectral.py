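"""Percent normalization, amplitude spectra, spectrograms and the
peak-ratio entrainment statistic.

The peak ratio at the stimulus frequency (PR0.25 for a 0.25 Hz stimulus)
is the single-sided amplitude-spectrum value at the stimulus frequency
divided by the mean amplitude over the 0.1–1 Hz vasomotion band.  A flat
spectrum gives exactly 1; stimulus-locked vasomotion pushes it well above
1, and segments with PR > 3 are conventionally treated as frequency-locked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .core import ImageStack, TraceSeries
from .vessel import _gaussian_kernel, _lowpass_extrapolated

__all__ = [
    "SpectralResult",
    "Spectrogram",
    "PeakRatioResult",
    "normalize_percent",
    "amplitude_spectrum",
    "spectrogram",
    "peak_ratio",
    "pr_map",
    "pulse_average",
]


@dataclass
class SpectralResult:
    """Single-sided amplitude spectrum: a pure sinusoid of amplitude A with
    an integer number of cycles appears as a peak of height A."""

    frequencies: np.ndarray  # Hz
    amplitudes: np.ndarray  # same units as the input trace (%)

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


@dataclass
class Spectrogram:
    """Short-term amplitude spectra at window centers."""

    times: np.ndarray  # s, window centers
    frequencies: np.ndarray  # Hz
    amplitudes: np.ndarray  # (n_times, n_freqs)
    window: float  # s
    step: float  # s

    def at_frequency(self, f0: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.frequencies - f0)))
        return self.amplitudes[:, i]


@dataclass
class PeakRatioResult:
    target_frequency: float  # Hz
    peak_amplitude: float  # %
    band_mean: float  # %
    pr: float  # dimensionless


def _baseline_fir(rate: float, passband_edge: float, stopband_edge: float) -> np.ndarray:
    """Linear-phase low-pass FIR passing below ``passband_edge`` and
    stopping above ``stopband_edge`` (Hamming design)."""
    width = stopband_edge - passband_edge
    if width <= 0:
        raise ValueError("stopband_edge must exceed passband_edge")
    numtaps = int(np.ceil(3.3 * rate / width))
    numtaps += 1 - numtaps % 2  # odd length -> exactly zero phase
    cutoff = 0.5 * (passband_edge + stopband_edge)
    return signal.firwin(numtaps, cutoff, fs=rate)


def slow_baseline(trace: TraceSeries, passband_edge: float = 0.01,
                  stopband_edge: float = 0.05) -> TraceSeries:
    """Slow multiplicative baseline of a raw fluorescence trace (photobleach
    fade and dye dilution), preserving only content below the passband edge."""
    kernel = _baseline_fir(trace.rate, passband_edge, stopband_edge)
    if trace.n < kernel.size:
        raise ValueError(
            f"trace of {trace.duration:.0f} s too short for the baseline filter")
    out = _lowpass_extrapolated(trace.values, kernel,
                                fit_len=min(trace.n, kernel.size),
                                presmooth=0.25 / stopband_edge * trace.rate)
    return trace.with_values(out, channel=f"{trace.channel}_baseline")


def normalize_percent(trace: TraceSeries, passband_edge: float = 0.01,
                      stopband_edge: float = 0.05) -> TraceSeries:
    """Fade-corrected percent-modulation trace.

    The raw fluorescence trace is divided by its own slow low-pass baseline
    (transition band between the two edges, default 10 -> 50 mHz), then 1
    is subtracted and the result scaled by 100.  Vasomotion-band content
    (>= 0.1 Hz) passes through untouched while the photobleach fade and the
    absolute fluorescence scale are removed.
    """
    if np.any(trace.values <= 0):
        raise ValueError("raw fluorescence trace must be strictly positive")
    if trace.duration < 60.0:
        raise ValueError("need at least 60 s of data to estimate a baseline")
    base = slow_baseline(trace, passband_edge, stopband_edge)
    if np.any(base.values <= 0):
        raise ValueError("estimated baseline is not strictly positive")
    out = (trace.values / base.values - 1.0) * 100.0
    return trace.with_values(out, channel=f"{trace.channel}_pct")


def amplitude_spectrum(trace: TraceSeries) -> SpectralResult:
    """Single-sided amplitude spectrum (rectangular window).

    Scaling: amplitude[k] = 2 |X_k| / N (DC and Nyquist bins unscaled by
    the factor 2), so an integer-cycle sinusoid of amplitude A yields a
    peak of exactly A at its frequency.
    """
    y = np.asarray(trace.values, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("trace contains NaN or infinite samples")
    n = y.size
    x = np.abs(np.fft.rfft(y)) / n
    amps = x.copy()
    amps[1:] *= 2.0
    if n % 2 == 0:
        amps[-1] = x[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / trace.rate)
    return SpectralResult(freqs, amps)


def spectrogram(trace: TraceSeries, window: float = 60.0,
                step: float = 4.0) -> Spectrogram:
    """Short-term Fourier transform with the amplitude-spectrum scaling.

    Conventional window/step pairs for a 0.25 Hz stimulus are 120/10, 60/4
    and 40/2 s; the 60 s window (15 stimulus cycles, 1/60 Hz resolution)
    with a 4 s (one-cycle) step is the default.
    """
    if window > trace.duration:
        raise ValueError("window longer than the trace")
    rate = trace.rate
    win_n = int(round(window * rate))
    step_n = max(1, int(round(step * rate)))
    n_bins = (trace.n - win_n) // step_n + 1
    freqs = np.fft.rfftfreq(win_n, d=1.0 / rate)
    amps = np.empty((n_bins, freqs.size))
    times = np.empty(n_bins)
    for i in range(n_bins):
        j = i * step_n
        seg = TraceSeries(trace.values[j:j + win_n], rate)
        amps[i] = amplitude_spectrum(seg).amplitudes
        times[i] = trace.t0 + (j + win_n / 2.0) / rate
    return Spectrogram(times, freqs, amps, window, step)


def peak_ratio(spec: SpectralResult, f0: float = 0.25,
               band: tuple[float, float] = (0.1, 1.0)) -> PeakRatioResult:
    """Peak-ratio statistic: amplitude at ``f0`` over the band mean.

    The peak is read at the bin nearest ``f0`` (exact when the trace
    duration is a multiple of 1/f0); the band mean runs over all bins in
    ``band`` inclusive of the f0 bin, so a flat spectrum scores exactly 1.
    """
    lo, hi = band
    if not lo <= f0 <= hi:
        raise ValueError(f"f0 = {f0} Hz outside band {band}")
    f = spec.frequencies
    if lo < f[0] or hi > f[-1]:
        raise ValueError(f"band {band} outside the spectrum range")
    i0 = int(np.argmin(np.abs(f - f0)))
    if abs(f[i0] - f0) > 0.51 * spec.df:
        warnings.warn(f"f0 = {f0} Hz is {abs(f[i0] - f0):.4f} Hz off the "
                      "nearest frequency bin")
    in_band = (f >= lo - 1e-12) & (f <= hi + 1e-12)
    peak = float(spec.amplitudes[i0])
    mean = float(spec.amplitudes[in_band].mean())
    return PeakRatioResult(f0, peak, mean, peak / mean)


def pr_map(stack: ImageStack, sigma_um: float = 165.0, f0: float = 0.25,
           band: tuple[float, float] = (0.1, 1.0),
           passband_edge: float = 0.01, stopband_edge: float = 0.05) -> np.ndarray:
    """Pixelwise peak-ratio map of a stack.

    Frames are spatially Gaussian-smoothed (sigma in µm), each pixel's time
    series is percent-normalized against its own slow baseline, Fourier
    transformed, and the peak ratio at ``f0`` computed.  Returns a (Y, X)
    float map.
    """
    if stack.pixel_size <= 0:
        raise ValueError("stack pixel_size required")
    if stack.n_frames / stack.frame_rate < 2.0 / band[0]:
        warnings.warn("stack shorter than two periods of the band low edge; "
                      "PR estimates will be unstable")
    rate = stack.frame_rate
    sigma_px = sigma_um / stack.pixel_size
    data = ndimage.gaussian_filter(stack.data, sigma=(0.0, sigma_px, sigma_px))

    n, ny, nx = data.shape
    flat = data.reshape(n, ny * nx)
    kernel = _baseline_fir(rate, passband_edge, stopband_edge)
    if n < kernel.size:
        raise ValueError("stack too short for the baseline filter")
    base = np.empty_like(flat)
    presmooth = 0.25 / stopband_edge * rate
    for p in range(flat.shape[1]):
        base[:, p] = _lowpass_extrapolated(flat[:, p], kernel,
                                           fit_len=min(n, kernel.size),
                                           presmooth=presmooth)
    if np.any(base <= 0):
        raise ValueError("non-positive baseline; expected raw fluorescence")
    pct = (flat / base - 1.0) * 100.0

    amps = np.abs(np.fft.rfft(pct, axis=0)) / n
    amps[1:] *= 2.0
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    i0 = int(np.argmin(np.abs(f - f0)))
    in_band = (f >= band[0] - 1e-12) & (f <= band[1] + 1e-12)
    pr = amps[i0] / amps[in_band].mean(axis=0)
    return pr.reshape(ny, nx)


def pulse_average(trace: TraceSeries, pulse_s: float = 0.02,
                  period_s: float = 0.2) -> TraceSeries:
    """Average a fast-sampled trace within periodic excitation pulses.

    Models pulsed-excitation acquisition: the detector samples continuously
    but only the samples within each ``pulse_s`` illumination window are
    averaged into one value per ``period_s`` cycle, so a 20 ms pulse every
    200 ms yields an effective rate of exactly 1 / period_s = 5 Hz.
    """
    if not 0 < pulse_s <= period_s:
        raise ValueError("need 0 < pulse_s <= period_s")
    per_pulse = max(1, int(round(pulse_s * trace.rate)))
    per_period = int(round(period_s * trace.rate))
    if abs(per_period - period_s * trace.rate) > 1e-9 or per_period < 1:
        raise ValueError("period must be an integer number of samples")
    n_out = trace.n // per_period
    idx = np.arange(n_out)[:, None] * per_period + np.arange(per_pulse)[None, :]
    vals = trace.values[idx].mean(axis=1)
    t0 = trace.t0 + 0.5 * (per_pulse - 1) / trace.rate  # mean pulse-sample time
    return TraceSeries(vals, 1.0 / period_s, channel=trace.channel, t0=t0)
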