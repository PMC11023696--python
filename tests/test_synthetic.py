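"""Generator contracts: construction examples, ground-truth fidelity and
seed determinism."""

import numpy as np
import pytest

from vasoentrain import synthetic as synth
from vasoentrain import spectral as sp
from vasoentrain.core import TraceSeries


class TestStimulus:
    def test_one_cycle_peak_to_peak(self):
        tr = synth.gen_stimulus(synth.StimulusSpec(duration=4.0), rate=5.0)
        assert tr.n == 20
        assert np.ptp(tr.values) == pytest.approx(17.0, rel=1e-3)

    def test_sample_count_scales_with_duration(self):
        tr = synth.gen_stimulus(synth.StimulusSpec(duration=300.0), rate=5.0)
        assert tr.n == 1500

    def test_starts_at_phase_zero(self):
        tr = synth.gen_stimulus(synth.StimulusSpec(duration=8.0), rate=20.0)
        assert tr.values[0] == 0.0
        assert tr.values[1] > 0

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_stimulus(synth.StimulusSpec(duration=10.0), rate=0.4)

    @pytest.mark.parametrize("bad", [dict(temporal_frequency=0.0),
                                     dict(duration=-1.0)])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            synth.StimulusSpec(**bad)


class TestEventTrace:
    def test_forced_event_shape(self):
        """A noiseless event has exactly the drawn peak and FWHM."""
        model = synth.EventModel(mean_interval=30.0, interval_sd=0.0,
                                 mean_peak=10.0, peak_sd=0.0,
                                 mean_halfwidth=1.6, halfwidth_sd=0.0)
        tr, gt = synth.gen_event_trace(model, 60.0, 5.0, noise_sd=0.0, seed=0)
        assert tr.values.max() == pytest.approx(10.0, abs=1e-9)
        # FWHM by interpolation on the noiseless trace
        y, t = tr.values, tr.time
        above = np.flatnonzero(y >= 5.0)
        i0, i1 = above[0], above[-1]
        left = t[i0 - 1] + (5.0 - y[i0 - 1]) / (y[i0] - y[i0 - 1]) * 0.2
        right = t[i1] + (y[i1] - 5.0) / (y[i1] - y[i1 + 1]) * 0.2
        assert right - left == pytest.approx(1.6, abs=0.02)

    def test_mean_drawn_interval_near_model(self, event_sessions):
        drawn = np.concatenate([np.diff(gt.params["onset_times"])
                                for _, gt in event_sessions])
        se = 4.8 / np.sqrt(drawn.size)
        assert abs(drawn.mean() - 15.8) < 2 * se

    def test_seed_determinism(self):
        a, _ = synth.gen_event_trace(synth.EventModel(), 300.0, 5.0, seed=42)
        b, _ = synth.gen_event_trace(synth.EventModel(), 300.0, 5.0, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_short_duration_warns_empty(self):
        model = synth.EventModel(mean_interval=15.8)
        with pytest.warns(UserWarning):
            tr, gt = synth.gen_event_trace(model, 16.0, 5.0, seed=1)

    def test_ground_truth_rebuilds_noiseless_trace(self):
        """The stored parameters are sufficient to regenerate the trace."""
        tr, gt = synth.gen_event_trace(synth.EventModel(), 300.0, 5.0,
                                       noise_sd=0.0, seed=3)
        t = tr.time
        rebuilt = np.zeros_like(tr.values)
        rise = gt.params["rise_s"]
        for pk_t, p, tau in zip(gt.params["peak_times"],
                                gt.params["peak_amplitudes"],
                                gt.params["taus"]):
            ramp = (t > pk_t - rise) & (t <= pk_t)
            rebuilt[ramp] += p * (t[ramp] - (pk_t - rise)) / rise
            decay = t > pk_t
            rebuilt[decay] += p * np.exp(-(t[decay] - pk_t) / tau)
        assert np.allclose(rebuilt, tr.values, atol=1e-9)


class TestPhotometryPair:
    def test_pure_mirror_truth_is_180(self):
        _, _, gt = synth.gen_photometry_pair(channel_lag=0.0, mirror=True,
                                             seed=0)
        assert gt.params["true_phase"] == pytest.approx(180.0)

    def test_autofluorescence_lag_truth(self):
        _, _, gt = synth.gen_photometry_pair(
            channel_lag=synth.AUTOFLUOR_CHANNEL_LAG_S, seed=0)
        assert gt.params["true_phase"] == pytest.approx(246.9, abs=1e-6)

    def test_lag_longer_than_cycle_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_photometry_pair(channel_lag=4.5, seed=0)

    def test_unlocked_pr_matches_amplitude_zero(self):
        """With lock_fraction 0 the trace's PR distribution is that of a
        no-oscillation trace."""
        from scipy.stats import mannwhitneyu
        stim = synth.StimulusSpec(duration=300.0)
        prs_unlocked, prs_silent = [], []
        for seed in range(25):
            c, _, _ = synth.gen_photometry_pair(
                stim, synth.EntrainmentModel(lock_fraction=0.0), seed=seed)
            prs_unlocked.append(sp.peak_ratio(
                sp.amplitude_spectrum(sp.normalize_percent(c))).pr)
            c, _, _ = synth.gen_photometry_pair(
                stim, synth.EntrainmentModel(locked_amplitude=0.0),
                seed=1000 + seed)
            prs_silent.append(sp.peak_ratio(
                sp.amplitude_spectrum(sp.normalize_percent(c))).pr)
        assert mannwhitneyu(prs_unlocked, prs_silent).pvalue > 0.01

    def test_seed_determinism(self):
        a1, a2, _ = synth.gen_photometry_pair(seed=5)
        b1, b2, _ = synth.gen_photometry_pair(seed=5)
        assert np.array_equal(a1.values, b1.values)
        assert np.array_equal(a2.values, b2.values)


class TestVesselStack:
    def test_noiseless_profile_closed_form(self):
        """FW10M of the projected cylinder is sqrt(0.99) * diameter."""
        stack, _ = synth.gen_vessel_stack(
            true_diameter=40.0, osc_amplitude=0.0, noise_sd=0.0,
            fade_tau=1e9, duration=1.0, seed=0)
        frame = stack.data[0]
        prof = frame[0] - frame[0].min()
        thr = 0.1 * prof.max()
        above = np.flatnonzero(prof > thr)
        x = np.arange(prof.size) * stack.pixel_size
        left = np.interp(thr, prof[above[0] - 1:above[0] + 1],
                         x[above[0] - 1:above[0] + 1])
        right = np.interp(thr, prof[above[-1]:above[-1] + 2][::-1],
                          x[above[-1]:above[-1] + 2][::-1])
        assert right - left == pytest.approx(40.0 * np.sqrt(0.99), abs=1.0)

    def test_per_frame_truth_is_sinusoid(self):
        _, gt = synth.gen_vessel_stack(osc_amplitude=10.0, osc_freq=0.25,
                                       duration=8.0, seed=0)
        d = np.asarray(gt.params["diameter_per_frame"])
        t = np.arange(d.size) / 5.0
        expect = 45.7 * (1 + 0.10 * np.sin(2 * np.pi * 0.25 * t))
        assert np.allclose(d, expect)

    def test_field_of_view_guard(self):
        with pytest.raises(ValueError):
            synth.gen_vessel_stack(true_diameter=45.7, field_factor=0.9,
                                   duration=1.0, seed=0)

    def test_minimum_resolution_guard(self):
        with pytest.raises(ValueError):
            synth.gen_vessel_stack(true_diameter=3.0, pixel_size=1.0,
                                   duration=1.0, seed=0)


class TestEyeTrace:
    def test_noiseless_trace_equals_scaled_stimulus(self):
        stim = synth.StimulusSpec(duration=20.0)
        tr, _ = synth.gen_eye_trace(stim, gain=1.0, phase_lag=0.0,
                                    saccade_rate=0.0, drift_amp=0.0,
                                    noise_sd=0.0, seed=0)
        expect = synth.gen_stimulus(stim, 30.0)
        assert np.allclose(tr.values, expect.values, atol=1e-9)

    def test_saccade_steps_exceed_one_degree(self):
        stim = synth.StimulusSpec(duration=300.0)
        tr, gt = synth.gen_eye_trace(stim, saccade_rate=6.0, noise_sd=0.0,
                                     drift_amp=0.0, seed=2)
        n_true = len(gt.params["saccade_times"])
        steps = np.abs(np.diff(tr.values))
        # brute force: count supra-threshold inter-frame steps
        assert np.sum(steps > 1.0) == n_true
        assert 15 <= n_true <= 50  # ~30 expected at 6/min over 5 min

    def test_gain_bounds_enforced(self):
        with pytest.raises(ValueError):
            synth.gen_eye_trace(gain=1.5, seed=0)

    def test_seed_determinism(self):
        a, ga = synth.gen_eye_trace(seed=9)
        b, gb = synth.gen_eye_trace(seed=9)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(ga.params["saccade_times"],
                              gb.params["saccade_times"])


def test_ground_truth_json_roundtrip(tmp_path):
    _, gt = synth.gen_event_trace(synth.EventModel(), 60.0, 5.0, seed=0)
    path = tmp_path / "gt.json"
    gt.to_json(path)
    back = synth.GroundTruth.from_json(path)
    assert back.kind == gt.kind and back.seed == gt.seed
    assert np.allclose(back.params["peak_amplitudes"],
                       gt.params["peak_amplitudes"])
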