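"""Synthetic data generators with stored ground truth.

Every input the analysis pipeline consumes can be generated here with known
ground truth: fluorescence photometry channel pairs entrained to a slow
oscillating visual stimulus, spontaneous vasodilation event traces, vessel
image stacks with an oscillating projected-cylinder cross-section, and eye
angle traces tracking the stimulus with saccades and drift.

Default parameters encode the experimental conditions the pipeline is
designed for: a vertical-stripe stimulus oscillating at 0.25 Hz with 17 deg
peak-to-peak visual-angle amplitude, 5 Hz effective fluorescence sampling,
spontaneous dilation events recurring every 15.8 +/- 4.8 s with
10.4 +/- 3.7 % peak amplitude and 1.6 +/- 0.4 s half-width, pial vessel
diameters around 45.7 um, and 30 fps eye tracking with a 2.3 deg lag.

All randomness flows through a single ``numpy`` Generator seeded by the
caller; identical arguments and seed reproduce outputs bit-identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
from scipy import stats

from .core import ImageStack, TraceSeries

__all__ = [
    "StimulusSpec",
    "EventModel",
    "EntrainmentModel",
    "GroundTruth",
    "DYFP_CHANNEL_LAG_S",
    "AUTOFLUOR_CHANNEL_LAG_S",
    "gen_stimulus",
    "gen_event_trace",
    "gen_photometry_pair",
    "gen_vessel_stack",
    "gen_eye_trace",
]

# Channel-lag defaults for the two parenchymal "shadow" channel models, in
# seconds at the 4 s stimulus cycle.  The directly excited YFP channel is an
# almost pure mirror of the intravascular dye (phase ~184.4 deg); the
# endogenous autofluorescence channel carries an additional metabolic delay
# (phase ~246.9 deg).  lag = (phase - 180) / 360 * cycle.
DYFP_CHANNEL_LAG_S = (184.4 - 180.0) / 360.0 * 4.0
AUTOFLUOR_CHANNEL_LAG_S = (246.9 - 180.0) / 360.0 * 4.0


@dataclass(frozen=True)
class StimulusSpec:
    """Oscillating visual stimulus descriptor.

    ``oscillation_amplitude`` is the peak-to-peak excursion in degrees of
    visual angle; the stimulus position is ``(A/2) sin(2 pi f t)``.
    """

    temporal_frequency: float = 0.25  # Hz
    oscillation_amplitude: float = 17.0  # deg, peak-to-peak
    spatial_cycle: float = 6.4  # deg per stripe cycle
    duration: float = 900.0  # s

    def __post_init__(self) -> None:
        if not self.temporal_frequency > 0:
            raise ValueError("temporal_frequency must be positive")
        if not self.duration > 0:
            raise ValueError("duration must be positive")

    @property
    def cycle(self) -> float:
        """Stimulus period in seconds."""
        return 1.0 / self.temporal_frequency


@dataclass(frozen=True)
class EventModel:
    """Spontaneous dilation-event statistics (means and SDs of the
    truncated-normal distributions the generator draws from)."""

    mean_interval: float = 15.8  # s between successive events
    interval_sd: float = 4.8
    mean_peak: float = 10.4  # % dilation above baseline
    peak_sd: float = 3.7
    mean_halfwidth: float = 1.6  # s, full width at half maximum
    halfwidth_sd: float = 0.4

    def __post_init__(self) -> None:
        for name in ("mean_interval", "mean_peak", "mean_halfwidth"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("interval_sd", "peak_sd", "halfwidth_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class EntrainmentModel:
    """Stimulus-locked oscillation model for photometry traces."""

    locked_amplitude: float = 3.0  # % modulation while frequency-locked
    lock_fraction: float = 1.0  # fraction of session spent in lock
    phase_offset: float = 0.0  # deg of channel 1 relative to stimulus
    fade_tau: float = 600.0  # s, photobleach time constant
    noise_sd: float = 1.0  # % of baseline fluorescence

    def __post_init__(self) -> None:
        if not 0.0 <= self.lock_fraction <= 1.0:
            raise ValueError("lock_fraction must be in [0, 1]")
        if not self.fade_tau > 0:
            raise ValueError("fade_tau must be positive")


@dataclass
class GroundTruth:
    """Record of every parameter a generator drew, sufficient to rebuild
    the noiseless output."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(_jsonable(asdict(self)), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(kind=d["kind"], seed=d["seed"], params=d["params"])


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, size: int,
               lower: float = 0.0) -> np.ndarray:
    """Normal(mean, sd) truncated below at ``lower``."""
    if sd == 0:
        return np.full(size, mean)
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def gen_stimulus(spec: StimulusSpec, rate: float) -> TraceSeries:
    """Sinusoidal stimulus position trace, phase 0 at t = 0.

    Returns a trace of ``round(duration * rate)`` samples in degrees of
    visual angle with semi-amplitude ``oscillation_amplitude / 2``.
    """
    if not rate > 0:
        raise ValueError("rate must be positive")
    if rate < 2.0 * spec.temporal_frequency:
        raise ValueError(
            f"rate {rate} Hz violates Nyquist for f = {spec.temporal_frequency} Hz")
    n = int(round(spec.duration * rate))
    t = np.arange(n) / rate
    values = 0.5 * spec.oscillation_amplitude * np.sin(
        2.0 * np.pi * spec.temporal_frequency * t)
    return TraceSeries(values, rate, channel="stimulus")


def gen_event_trace(model: EventModel, duration: float, rate: float,
                    noise_sd: float = 0.5, seed: int = 0,
                    rise_s: float | None = None,
                    ) -> tuple[TraceSeries, GroundTruth]:
    """Baseline-0 % trace of spontaneous dilation transients.

    Each event rises linearly over one sample interval (near-instantaneous
    at the slow event timescale) and decays exponentially; the decay
    constant is chosen so the transient's continuous-time full width at
    half maximum equals the drawn half-width:
    ``tau = (halfwidth - rise/2) / ln 2``.  Event onsets are snapped to the
    sampling grid so drawn peak amplitudes are realized exactly at a sample.

    Intervals, peaks and half-widths are drawn from normal distributions
    truncated at zero (half-widths at the rise time).
    """
    if not duration > model.mean_interval:
        raise ValueError("duration must exceed the mean inter-event interval")
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate
    if rise_s is None:
        rise_s = dt
    n = int(round(duration * rate))
    t = np.arange(n) * dt

    # Sequential event times; draw generously then truncate to duration.
    n_max = max(4, int(2 * duration / model.mean_interval) + 8)
    intervals = _truncnorm(rng, model.mean_interval, model.interval_sd, n_max)
    onset_cont = np.cumsum(intervals)
    onset_cont = onset_cont[onset_cont < duration - 2.0 * model.mean_halfwidth]
    onset_idx = np.round(onset_cont * rate).astype(int)
    n_ev = onset_idx.size
    if n_ev == 0:
        warnings.warn("duration too short to host one event; empty trace")
    peaks = _truncnorm(rng, model.mean_peak, model.peak_sd, n_ev)
    halfwidths = _truncnorm(rng, model.mean_halfwidth, model.halfwidth_sd,
                            n_ev, lower=rise_s)
    taus = (halfwidths - 0.5 * rise_s) / np.log(2.0)

    values = np.zeros(n)
    rise_n = max(1, int(round(rise_s * rate)))
    for i in range(n_ev):
        k0 = onset_idx[i]
        kp = k0 + rise_n
        if kp >= n:
            continue
        ramp = peaks[i] * np.arange(1, rise_n + 1) / rise_n
        values[k0 + 1:kp + 1] += ramp[:max(0, n - k0 - 1)]
        decay_t = t[kp + 1:] - t[kp]
        values[kp + 1:] += peaks[i] * np.exp(-decay_t / taus[i])
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, n)

    gt = GroundTruth(kind="event_trace", seed=seed, params=dict(
        model=asdict(model), duration=duration, rate=rate, noise_sd=noise_sd,
        rise_s=rise_s,
        onset_times=(onset_idx * dt),
        peak_times=((onset_idx + rise_n) * dt),
        peak_amplitudes=peaks, halfwidths=halfwidths, taus=taus))
    return TraceSeries(values, rate, channel="diameter_pct"), gt


def _lock_mask(rng: np.random.Generator, n: int, rate: float,
               lock_fraction: float, mean_epoch_pair: float = 80.0) -> np.ndarray:
    """Binary in-lock mask: alternating locked/unlocked epochs with
    exponential durations; ``lock_fraction`` sets the duty cycle."""
    if lock_fraction >= 1.0:
        return np.ones(n)
    if lock_fraction <= 0.0:
        return np.zeros(n)
    mean_locked = lock_fraction * mean_epoch_pair
    mean_unlocked = (1.0 - lock_fraction) * mean_epoch_pair
    mask = np.zeros(n)
    locked = bool(rng.random() < lock_fraction)
    i = 0
    while i < n:
        mean = mean_locked if locked else mean_unlocked
        length = max(1, int(round(rng.exponential(mean) * rate)))
        if locked:
            mask[i:i + length] = 1.0
        i += length
        locked = not locked
    return mask


def gen_photometry_pair(stim: StimulusSpec | None = None,
                        ent: EntrainmentModel | None = None,
                        channel_lag: float = DYFP_CHANNEL_LAG_S,
                        mirror: bool = True,
                        rate: float = 5.0,
                        seed: int = 0,
                        ) -> tuple[TraceSeries, TraceSeries, GroundTruth]:
    """Two raw fluorescence channels sharing a stimulus-locked oscillation.

    Channel 1 models an intravascular dye: baseline x (1 + stimulus-locked
    percent modulation) x photobleach fade + noise.  Channel 2 models a
    parenchymal shadow channel: the same modulation, inverted when
    ``mirror`` is set, delayed by ``channel_lag`` seconds, with its own
    fade constant and independent noise.

    The ground-truth phase of channel 2 relative to channel 1 is
    ``180 * mirror + channel_lag / cycle * 360`` degrees.
    """
    stim = stim or StimulusSpec()
    ent = ent or EntrainmentModel()
    if rate < 2.0 * stim.temporal_frequency:
        raise ValueError("rate violates Nyquist for the stimulus frequency")
    if abs(channel_lag) >= stim.cycle:
        raise ValueError("channel_lag must be smaller than the stimulus period")
    rng = np.random.default_rng(seed)
    n = int(round(stim.duration * rate))
    t = np.arange(n) / rate
    w = 2.0 * np.pi * stim.temporal_frequency
    phi = np.deg2rad(ent.phase_offset)
    a = ent.locked_amplitude / 100.0

    mask = _lock_mask(rng, n, rate, ent.lock_fraction)
    lag_n = int(round(channel_lag * rate))
    mask2 = np.roll(mask, lag_n) if lag_n else mask

    mod1 = a * mask * np.sin(w * t + phi)
    sign = -1.0 if mirror else 1.0
    mod2 = sign * a * mask2 * np.sin(w * (t - channel_lag) + phi)

    f0_1, f0_2 = 1000.0, 800.0
    tau2 = 1.2 * ent.fade_tau  # each channel bleaches at its own pace
    sd = ent.noise_sd / 100.0
    ch1 = f0_1 * ((1.0 + mod1) * np.exp(-t / ent.fade_tau)
                  + sd * rng.normal(size=n))
    ch2 = f0_2 * ((1.0 + mod2) * np.exp(-t / tau2)
                  + sd * rng.normal(size=n))

    true_phase = (180.0 * bool(mirror)
                  + channel_lag / stim.cycle * 360.0) % 360.0
    gt = GroundTruth(kind="photometry_pair", seed=seed, params=dict(
        stim=asdict(stim), ent=asdict(ent), channel_lag=channel_lag,
        mirror=bool(mirror), rate=rate, true_phase=true_phase,
        lock_mask=mask, baseline_1=f0_1, baseline_2=f0_2,
        fade_tau_1=ent.fade_tau, fade_tau_2=tau2))
    return (TraceSeries(ch1, rate, channel="texasred"),
            TraceSeries(ch2, rate, channel="shadow"), gt)


def gen_vessel_stack(true_diameter: float = 45.7,
                     osc_amplitude: float = 5.0,
                     osc_freq: float = 0.1,
                     events: EventModel | None = None,
                     fade_tau: float = 600.0,
                     pixel_size: float = 1.0,
                     rate: float = 5.0,
                     duration: float = 60.0,
                     noise_sd: float = 1.0,
                     seed: int = 0,
                     height: int = 32,
                     field_factor: float = 2.5,
                     ) -> tuple[ImageStack, GroundTruth]:
    """Time-lapse stack of a vertical fluorescent vessel.

    The vessel is a bright vertical band on a dim parenchyma background
    (intravascular-dye convention).  Because no optical sectioning is
    modeled, the cross-section follows the projected-cylinder profile
    ``I(x) = I0 sqrt(1 - (2x/d)^2)``, whose full width at 10 % of maximum
    is ``sqrt(0.99) d``.  The diameter oscillates sinusoidally at
    ``osc_freq`` with ``osc_amplitude`` percent semi-amplitude and
    optionally carries spontaneous dilation events; the whole frame fades
    as ``exp(-t / fade_tau)``.

    ``noise_sd`` is Gaussian pixel noise in percent of the in-vessel peak
    intensity.  The per-frame true diameter is stored in the ground truth.
    """
    if true_diameter < 4.0 * pixel_size:
        raise ValueError("true_diameter must be at least 4 pixels")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate

    d = np.full(n, float(true_diameter))
    d *= 1.0 + osc_amplitude / 100.0 * np.sin(2.0 * np.pi * osc_freq * t)
    event_gt = None
    if events is not None:
        ev_trace, event_gt = gen_event_trace(events, duration, rate,
                                             noise_sd=0.0, seed=seed + 1)
        d *= 1.0 + ev_trace.values / 100.0

    width = int(np.ceil(field_factor * true_diameter / pixel_size))
    if d.max() >= width * pixel_size:
        raise ValueError("vessel diameter exceeds the field of view")
    cx = (width - 1) / 2.0
    x_um = (np.arange(width) - cx) * pixel_size

    # Projection physics: intensity is proportional to the chord length
    # through the dye-filled lumen, d * sqrt(1 - (2x/d)^2), so the peak
    # brightens as the vessel dilates (this is what couples the diameter
    # and peak-intensity readouts).
    peak, background = 1000.0, 100.0
    u = 2.0 * x_um[None, :] / d[:, None]
    profile = (peak * (d / true_diameter)[:, None]
               * np.sqrt(np.clip(1.0 - u * u, 0.0, None)))
    frames = (profile[:, None, :] + background) * np.exp(-t / fade_tau)[:, None, None]
    frames = np.broadcast_to(frames, (n, height, width)).copy()
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd / 100.0 * peak, frames.shape)

    gt = GroundTruth(kind="vessel_stack", seed=seed, params=dict(
        true_diameter=true_diameter, osc_amplitude=osc_amplitude,
        osc_freq=osc_freq, fade_tau=fade_tau, pixel_size=pixel_size,
        rate=rate, duration=duration, noise_sd=noise_sd,
        peak_intensity=peak, background=background,
        diameter_per_frame=d,
        events=None if event_gt is None else event_gt.params))
    return ImageStack(frames, pixel_size, rate, channel="texasred"), gt


def gen_eye_trace(stim: StimulusSpec | None = None,
                  gain: float = 0.5,
                  phase_lag: float = 2.3,
                  saccade_rate: float = 6.0,
                  drift_amp: float = 2.0,
                  noise_sd: float = 0.1,
                  frame_rate: float = 30.0,
                  seed: int = 0,
                  ) -> tuple[TraceSeries, GroundTruth]:
    """Horizontal eye-angle trace tracking the oscillating stimulus.

    eye(t) = gain * stimulus(t delayed by phase_lag deg) + slow sinusoidal
    drift + Gaussian noise + Poisson-timed saccades.  Each saccade is an
    instantaneous step larger than 1 deg followed by exponential
    re-centering (tau = 0.5 s), so only the onset frame carries a
    supra-threshold inter-frame step.

    ``phase_lag`` is in degrees of the stimulus cycle (positive = eye lags
    the stimulus); ``saccade_rate`` is per minute.
    """
    stim = stim or StimulusSpec()
    if not 0.0 <= gain <= 1.2:
        raise ValueError("gain must be within [0, 1.2]")
    rng = np.random.default_rng(seed)
    n = int(round(stim.duration * frame_rate))
    t = np.arange(n) / frame_rate
    w = 2.0 * np.pi * stim.temporal_frequency

    tracking = gain * 0.5 * stim.oscillation_amplitude * np.sin(
        w * t - np.deg2rad(phase_lag))

    f_d = rng.uniform(0.003, 0.01)
    phi_d = rng.uniform(0.0, 2.0 * np.pi)
    drift = drift_amp * np.sin(2.0 * np.pi * f_d * t + phi_d)

    n_sac = rng.poisson(saccade_rate * stim.duration / 60.0)
    sac_idx = np.sort(rng.integers(1, n - 1, size=n_sac))
    sac_amp = rng.uniform(1.5, 4.0, size=n_sac) * rng.choice([-1.0, 1.0], size=n_sac)
    tau_r = 0.5
    saccadic = np.zeros(n)
    for k, a in zip(sac_idx, sac_amp):
        saccadic[k:] += a * np.exp(-(t[k:] - t[k]) / tau_r)

    values = tracking + drift + saccadic
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, n)

    gt = GroundTruth(kind="eye_trace", seed=seed, params=dict(
        stim=asdict(stim), gain=gain, phase_lag=phase_lag,
        saccade_rate=saccade_rate, drift_amp=drift_amp, noise_sd=noise_sd,
        frame_rate=frame_rate, saccade_times=(sac_idx / frame_rate),
        saccade_amplitudes=sac_amp, drift_freq=f_d, drift_phase=phi_d))
    return TraceSeries(values, frame_rate, channel="eye_deg"), gt
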