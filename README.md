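# vasoentrain

Analysis pipeline for **stimulus-entrained vasomotion**: slow (~0.1–0.25 Hz)
oscillations of cerebral vessel diameter that can frequency-lock to a slowly
oscillating visual stimulus, measured through wide-field fluorescence
imaging and fiber photometry, together with the horizontal optokinetic
response (HOKR) eye movements the same stimulus drives.

The package is for experimenters who record:

- **vessel image stacks** (an intravascular dye such as TexasRed, vessel
  aligned vertically) and want per-frame diameter and peak-intensity series,
- **fluorescence traces** (intravascular dye and/or parenchymal "shadow"
  channels, 5 Hz effective sampling) and want to quantify how strongly and
  at what phase the signal locks to the stimulus,
- **eye-angle traces** (30 fps) and want HOKR amplitude and relative gain
  across a training schedule.

Every input can also be *generated synthetically* with known ground truth
(`vasoentrain.synthetic`), so each stage of the pipeline is verifiable
without any recording.

## The quantities at the core

**FW10M diameter.** A cross-section intensity profile of a dye-filled
vessel imaged without optical sectioning follows the projected-cylinder
form I(x) ∝ √(1 − (2x/d)²). The vessel diameter index is the full width of
the profile at 10 % of its maximum; analytically FW10M = √0.99 · d, so an
absolute estimate divides by √0.99. Dynamics are reported relative to the
basal (undilated-phase) value.

**Dilation events.** Spontaneous vasodilation transients (near-instant
rise, exponential decay) are detected by thresholding the
baseline-normalized diameter (or shadow-intensity) trace and summarized by
inter-event interval (peak to peak), peak amplitude (%), and unit dilation
time (full width at half of peak amplitude).

**PR0.25 — the entrainment statistic.** After percent normalization
(dividing the raw trace by its own slow low-pass baseline, which removes
photobleach fade), the single-sided amplitude spectrum A(f) is computed and

    PR(f₀) = A(f₀) / mean{ A(f) : 0.1 Hz ≤ f ≤ 1 Hz },   f₀ = 0.25 Hz.

A flat spectrum gives PR = 1; segments with PR > 3 are treated as
frequency-locked.

**Phase.** For mirrored channel pairs, the lag Δt of the negative
cross-correlation peak near 0 converts to phase = (Δt/T)·360° + 180°
(T = 4 s stimulus cycle). For stimulus-locked responses, the trace is cut
into T-long segments (75 segments per 5 min), averaged, and fitted with a
fixed-frequency sinusoid.

**HOKR gain.** Eye traces are cleaned of saccades (inter-frame steps
> 1°), bandpassed at 100–500 mHz, and the oscillation amplitude is the mean
per-cycle maximum minus the mean per-cycle minimum; relative gain
normalizes each test to the first test of the first training session.

## Worked example

```python
import numpy as np
from vasoentrain import synthetic as synth, spectral as sp, phase as ph

# a 900 s, 5 Hz photometry pair: stimulus-locked dye channel plus a
# mirrored parenchymal shadow channel, with photobleach fade and noise
ch1, ch2, truth = synth.gen_photometry_pair(seed=1)

pct1 = sp.normalize_percent(ch1)          # percent modulation, fade removed
spec = sp.amplitude_spectrum(pct1)
pr = sp.peak_ratio(spec, f0=0.25)
print(f"PR0.25 = {pr.pr:.1f}")

dt = ph.crosscorr_lag(pct1, sp.normalize_percent(ch2), max_lag=4.0)
print(f"delta_t = {dt:.2f} s -> phase = {ph.phase_from_lag(dt, 4.0):.1f} deg "
      f"(truth {truth.params['true_phase']:.1f})")
```

prints

```
PR0.25 = 43.3
delta_t = 0.00 s -> phase = 180.0 deg (truth 184.4)
```

The peak ratio of ~43 says the 0.25 Hz amplitude stands ~43× above the
vasomotion-band mean — a strongly locked trace. The estimated phase is
180.0°: the shadow channel mirrors the dye channel; the 4.4° gap to the
generated truth is below one lag quantum (a 0.2 s sample on a 4 s cycle =
18°), the resolution of the 5 Hz cross-correlation estimate.

The same works from a shell:

```bash
vasoentrain simulate photometry --seed 1 --out sim/
vasoentrain spectral sim/channel1.csv --f0 0.25
vasoentrain phase sim/channel1.csv sim/channel2.csv --cycle 4
```

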