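"""Percent normalization, spectra, peak ratio and the pixelwise PR map."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vasoentrain import spectral as sp
from vasoentrain import synthetic as synth
from vasoentrain.core import ImageStack, TraceSeries


def _sine_trace(amp_pct=5.0, f=0.25, duration=300.0, rate=5.0, base=1000.0):
    t = np.arange(0, duration, 1 / rate)
    return TraceSeries(base * (1 + amp_pct / 100 * np.sin(2 * np.pi * f * t)),
                       rate)


class TestNormalizePercent:
    def test_constant_trace_becomes_zero(self):
        out = sp.normalize_percent(TraceSeries(np.full(1500, 800.0), 5.0))
        assert np.allclose(out.values, 0.0, atol=1e-9)

    def test_modulation_depth_preserved(self):
        out = sp.normalize_percent(_sine_trace(5.0))
        spec = sp.amplitude_spectrum(out)
        i = np.argmin(np.abs(spec.frequencies - 0.25))
        assert spec.amplitudes[i] == pytest.approx(5.0, rel=0.02)

    def test_fade_leaves_no_trend(self, default_pair):
        ch1, _, _ = default_pair
        out = sp.normalize_percent(ch1)
        minutes = np.arange(out.n) / out.rate / 60.0
        slope = np.polyfit(minutes, out.values, 1)[0]
        assert abs(slope) < 0.01  # % per minute

    def test_nonpositive_input_rejected(self):
        tr = TraceSeries(np.linspace(-1, 10, 1500), 5.0)
        with pytest.raises(ValueError):
            sp.normalize_percent(tr)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            sp.normalize_percent(TraceSeries(np.full(100, 5.0), 5.0))


class TestAmplitudeSpectrum:
    def test_integer_cycle_sinusoid_exact_peak(self):
        t = np.arange(0, 300, 0.2)
        tr = TraceSeries(3.0 * np.sin(2 * np.pi * 0.25 * t), 5.0)
        spec = sp.amplitude_spectrum(tr)
        i = np.argmax(spec.amplitudes)
        assert spec.frequencies[i] == pytest.approx(0.25, abs=1e-12)
        assert spec.amplitudes[i] == pytest.approx(3.0, rel=1e-9)

    def test_parseval(self, rng):
        y = rng.normal(size=1000)
        spec = sp.amplitude_spectrum(TraceSeries(y, 5.0))
        # single-sided amplitude scaling: mean power = A0^2 + sum(Ak^2)/2
        rhs = spec.amplitudes[0] ** 2 \
            + 0.5 * np.sum(spec.amplitudes[1:-1] ** 2) \
            + spec.amplitudes[-1] ** 2
        assert np.mean(y ** 2) == pytest.approx(rhs, rel=1e-6)

    def test_white_noise_has_no_dominant_bin(self, rng):
        hits = 0
        for _ in range(50):
            spec = sp.amplitude_spectrum(TraceSeries(rng.normal(size=1500), 5.0))
            band = (spec.frequencies >= 0.1) & (spec.frequencies <= 1.0)
            if spec.amplitudes[band].max() > 5 * spec.amplitudes[band].mean():
                hits += 1
        assert hits <= 2  # > 5x band mean is very rare for white noise

    def test_nan_rejected(self):
        y = np.ones(1500)
        y[3] = np.nan
        with pytest.raises(ValueError):
            sp.amplitude_spectrum(TraceSeries(y, 5.0))

    def test_entrained_generator_peaks_at_stimulus_frequency(self, default_pair):
        ch1, _, _ = default_pair
        spec = sp.amplitude_spectrum(sp.normalize_percent(ch1))
        i = 1 + np.argmax(spec.amplitudes[1:])
        assert spec.frequencies[i] == pytest.approx(0.25, abs=1e-12)


class TestSpectrogram:
    def test_bin_count(self):
        tr = TraceSeries(np.sin(2 * np.pi * 0.25 * np.arange(4500) / 5), 5.0)
        sg = sp.spectrogram(tr, window=60.0, step=4.0)
        assert sg.amplitudes.shape[0] == (900 - 60) // 4 + 1 == 211

    def test_stationary_sinusoid_constant_row(self):
        tr = TraceSeries(2 * np.sin(2 * np.pi * 0.25 * np.arange(3000) / 5), 5.0)
        sg = sp.spectrogram(tr, 60.0, 4.0)
        row = sg.at_frequency(0.25)
        assert row.std() / row.mean() < 0.05

    def test_intermittent_lock_modulates_row(self):
        stim = synth.StimulusSpec(duration=600.0)
        ent = synth.EntrainmentModel(lock_fraction=0.5, noise_sd=0.3)
        ch1, _, gt = synth.gen_photometry_pair(stim, ent, seed=12)
        sg = sp.spectrogram(sp.normalize_percent(ch1), 40.0, 4.0)
        row = sg.at_frequency(0.25)
        mask = np.asarray(gt.params["lock_mask"])
        # classify windows by their ground-truth lock occupancy
        occ = np.array([mask[int((t - 20) * 5):int((t + 20) * 5)].mean()
                        for t in sg.times])
        locked, unlocked = row[occ > 0.8], row[occ < 0.2]
        assert locked.size and unlocked.size
        assert locked.mean() > 2 * unlocked.mean()

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            sp.spectrogram(TraceSeries(np.ones(100), 5.0), window=60.0)


class TestPeakRatio:
    def test_flat_spectrum_gives_one(self):
        f = np.linspace(0, 2.5, 751)
        spec = sp.SpectralResult(f, np.full(751, 3.3))
        assert sp.peak_ratio(spec).pr == pytest.approx(1.0)

    def test_single_elevated_bin_arithmetic(self):
        f = np.arange(0, 2.5, 1 / 300)
        a = np.ones_like(f)
        i0 = np.argmin(np.abs(f - 0.25))
        a[i0] = 10.0
        band = (f >= 0.1) & (f <= 1.0)
        B = band.sum()
        pr = sp.peak_ratio(sp.SpectralResult(f, a)).pr
        assert pr == pytest.approx(10 * B / (B + 9), rel=1e-9)

    @settings(derandomize=True, max_examples=20)
    @given(scale=st.floats(0.01, 50.0))
    def test_scalar_invariance(self, scale):
        f = np.arange(0, 2.5, 1 / 300)
        a = 1.0 + 0.5 * np.sin(7 * f) ** 2
        pr1 = sp.peak_ratio(sp.SpectralResult(f, a)).pr
        pr2 = sp.peak_ratio(sp.SpectralResult(f, scale * a)).pr
        assert pr2 == pytest.approx(pr1, rel=1e-12)

    def test_f0_outside_band_rejected(self):
        f = np.arange(0, 2.5, 1 / 300)
        with pytest.raises(ValueError):
            sp.peak_ratio(sp.SpectralResult(f, np.ones_like(f)), f0=2.0)

    def test_pr_monotone_in_locked_amplitude(self):
        stim = synth.StimulusSpec(duration=300.0)
        prs = []
        for amp in (0.5, 1.5, 3.0, 6.0):
            ch1, _, _ = synth.gen_photometry_pair(
                stim, synth.EntrainmentModel(locked_amplitude=amp), seed=21)
            prs.append(sp.peak_ratio(
                sp.amplitude_spectrum(sp.normalize_percent(ch1))).pr)
        assert np.all(np.diff(prs) > 0)

    def test_noise_pr_distribution_stable(self):
        """PR of no-oscillation traces sits near 1 with modest spread."""
        stim = synth.StimulusSpec(duration=300.0)
        prs = [sp.peak_ratio(sp.amplitude_spectrum(sp.normalize_percent(
            synth.gen_photometry_pair(
                stim, synth.EntrainmentModel(locked_amplitude=0.0),
                seed=s)[0]))).pr
            for s in range(20)]
        assert 0.7 < np.mean(prs) < 1.5
        assert np.std(prs) < 1.0


class TestPRMap:
    def _stack(self, locked_cols, duration=120.0, seed=0):
        """Small raw stack: every pixel fades + noise; ``locked_cols``
        columns also carry the stimulus-locked oscillation."""
        rng = np.random.default_rng(seed)
        n = int(duration * 5)
        t = np.arange(n) / 5.0
        osc = 0.03 * np.sin(2 * np.pi * 0.25 * t)
        fade = np.exp(-t / 600.0)
        data = np.empty((n, 4, 16))
        for x in range(16):
            m = osc if x in locked_cols else 0.0
            data[:, :, x] = (1000 * (1 + m) * fade)[:, None]
        data += rng.normal(0, 5.0, data.shape)
        return ImageStack(data, 10.0, 5.0)

    def test_uniform_entrainment_uniform_map(self):
        stack = self._stack(locked_cols=range(16))
        m = sp.pr_map(stack, sigma_um=10.0)
        assert m.std() / m.mean() < 0.10

    def test_half_field_contrast(self):
        stack = self._stack(locked_cols=range(8))
        m = sp.pr_map(stack, sigma_um=10.0)
        assert m[:, :6].mean() > 2 * m[:, 10:].mean()

    def test_all_noise_map_near_one(self):
        stack = self._stack(locked_cols=())
        m = sp.pr_map(stack, sigma_um=10.0)
        assert 0.5 < m.mean() < 2.0


def test_pulse_averaging_gives_exactly_5hz():
    """20 ms pulses repeated every 200 ms average to a 5 Hz series."""
    t = np.arange(0, 10, 1 / 5000)
    tr = TraceSeries(np.sin(2 * np.pi * 0.25 * t), 5000.0)
    out = sp.pulse_average(tr, pulse_s=0.02, period_s=0.2)
    assert out.rate == 5.0
    assert out.n == 50
    expect = np.sin(2 * np.pi * 0.25 * (np.arange(50) * 0.2 + out.t0))
    assert np.allclose(out.values, expect, atol=1e-4)
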