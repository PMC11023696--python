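# Methods

This note documents the models, procedures and numerical choices behind
`vasoentrain`: what each stage assumes, which parameters matter and why
their defaults are what they are, what the synthetic generators do and do
not emulate, and where the design was genuinely open.

## 1. Signal model and study conditions

The pipeline targets recordings made under a fixed stimulation protocol: a
vertical-stripe pattern oscillating horizontally as a sinusoid with 0.25 Hz
temporal frequency, 17° peak-to-peak visual-angle amplitude, and 6.4°
spatial cycle. Fluorescence channels are sampled at an effective 5 Hz
(pulsed excitation: signals averaged within 20 ms pulses repeated every
200 ms, hence exactly 1/0.2 s = 5 Hz); eye videos run at 30 fps.

A raw fluorescence trace is modeled as

    F(t) = F₀ · (1 + m(t)) · b(t) + ε(t)

where `m(t)` is the physiological percent modulation (vasomotion, dilation
events, stimulus-locked oscillation), `b(t)` a slow multiplicative baseline
(photobleaching and dye dilution, time constants of hundreds of seconds),
and `ε` sensor noise. All spectral statistics operate on the percent
modulation `100·(F/lowpass(F) − 1)`, which removes both `b(t)` and the
absolute scale `F₀`.

## 2. Vessel imaging chain

Assumptions: one vessel per stack, pre-rotated so blood flow runs along the
image's vertical axis; no motion correction (out of scope); intensities in
arbitrary units.

1. **Background subtraction** — the mean over two user-supplied rectangular
   ROIs left and right of the vessel is computed per frame and that scalar
   subtracted from every pixel of the frame. Pixel noise may go negative
   afterwards; downstream code tolerates this.
2. **Fade baseline** — the mean intensity of an in-vessel ROI is low-pass
   filtered with a zero-phase Gaussian at 5 mHz (half-amplitude
   convention, σ ≈ 37.5 s), leaving only the bleaching decline; every frame
   is divided by this baseline. Vasomotion-band content (≥ 0.05 Hz) is
   suppressed by many orders of magnitude.
3. **Profiles** — rows perpendicular to the vessel are averaged per frame
   (noise falls as 1/√k for k rows), Gaussian-smoothed along position
   (default σ = 1 pixel), and slope-flattened by subtracting the straight
   line through the means of the two off-vessel flanks (outer 15 % of
   positions each side), since the two sides often sit at different
   background levels.
4. **FW10M** — the width between the outermost crossings of 10 % of the
   profile maximum, crossings interpolated linearly between samples. For
   the projected-cylinder profile I(x) ∝ √(1 − (2x/d)²) this equals
   √0.99·d exactly, so absolute estimates are divided by √0.99.

Open design points and the choices made:

- *Threshold reference.* Whether the 10 % level should be recomputed per
  frame or fixed per session is ambiguous. We fix it at 10 % of the
  basal-phase profile maximum, held across all frames, so that dilation
  reads as a width increase rather than being partially renormalized away.
- *Basal phase.* "Undilated" is operationalized as the lowest-quartile
  frames of the lightly smoothed first-pass diameter series; their mean
  profile defines the reference threshold, diameter and peak intensity
  (both output series are percent of basal, 100 = basal).
- *Profile smoothing.* A σ of 0.05 pixel would be a no-op; the default is
  1 pixel with the parameter exposed.

## 3. Dilation-event detection

Events are contiguous supra-threshold excursions of the baseline-normalized
trace; each prominent local peak within an excursion is one event
(overlaps split at the local minimum between peaks, with a prominence floor
equal to the threshold so noise wiggles cannot split a single event). Peak
amplitude is read from the raw trace; half-width (full width at half the
peak amplitude) is measured by linear interpolation on a 3-sample
boxcar-smoothed copy — on the slow decay flank the raw trace's noise would
otherwise trigger systematically early crossings and bias half-widths low
by several percent. Events whose half-maximum crossings cannot be resolved
inside the trace (or inside their own excursion) are discarded.

The automatic threshold is `k × 1.4826·median(|Δx|)/√2` (default k = 3): a
robust noise SD from successive differences. The plain MAD of the trace is
*not* used because the dilation transients themselves occupy roughly a
third of a typical session and inflate it about two-fold, which at k = 3
would silently discard the smallest ~8 % of events and bias the interval
and amplitude statistics beyond their recovery tolerance. Inter-event
intervals are peak-to-peak (peaks localize better than onsets on noisy
data). Summary curves are per-session cumulative relative frequencies on a
common grid, averaged across sessions.

## 4. Spectral analysis

- **Percent normalization** divides by a zero-phase FIR low-pass baseline
  with transition band 10 → 50 mHz (Hamming design, odd length, ~83 s at
  5 Hz). The recorded specification of this filter reads with pass- and
  stop-band inverted; it is implemented as a *baseline* low-pass so that
  0.25 Hz content passes untouched — any other reading would destroy the
  analyzed signal.
- **Edge handling.** All zero-phase low-pass filters here pad by *linear
  extrapolation* of a line fitted at each end, not by reflection: a
  monotone exponential fade reflected at the edge develops a kink that
  biases the baseline several percent low at the boundaries. The edge fit
  is computed on a pre-smoothed copy (and clear of the pre-smoother's own
  edge transient) so oscillation-band content cannot tilt the
  extrapolation.
- **Amplitude spectrum**: single-sided, rectangular window, scaled so an
  integer-cycle sinusoid of amplitude A yields a peak of exactly A.
  Session durations are cycle multiples by design, so 0.25 Hz is an exact
  bin. Parseval holds to machine precision.
- **Spectrogram**: same per-window scaling; window/step defaults 60 s/4 s
  (middle of the conventional 120/10, 60/4, 40/2 set), timestamps at
  window centers.
- **Peak ratio**: amplitude at the bin nearest f₀ over the mean across all
  bins in [0.1, 1] Hz *including* the f₀ bin (a flat spectrum then scores
  exactly 1; exclusion of the peak bin was the other defensible reading).
  PR is invariant to positive rescaling of the trace.
- **PR maps**: frames spatially Gaussian-smoothed (default σ = 165 µm),
  then the per-pixel time series runs through the same normalize → FFT →
  PR chain. Stacks shorter than two periods of the band's low edge warn
  rather than fail.

## 5. Phase analysis

For channel pairs, the normalized cross-correlation is searched in
[−T, +T] for local minima strictly inside the window; the most negative
wins, ties break toward the smallest |Δt|. A minimum only qualifies if it
falls below −3/√n — three times the correlation floor of independent white
traces — so a positively correlated pair is excluded (no phase) instead of
being assigned a lag from a noise wiggle. Phase = (Δt/T)·360° + 180°,
wrapped to [0, 360); the map is antisymmetric about 180°. At 5 Hz and
T = 4 s the lag grid quantizes phase to 18° steps; optional parabolic
interpolation around the minimum (off by default, matching the quantized
convention) recovers sub-sample lags.

For stimulus-locked responses, the trace is cut at stimulus-cycle
boundaries (rate and cycle must be commensurate), segments averaged, and
`A·sin(2πt/T + φ) + c` fitted with frequency fixed — linear in the sin/cos
basis, solved in closed form, exact on noiseless input. Reported lag is
−φ. Segment screening keeps 40 s windows (ten stimulus cycles; f₀ lands on
an exact bin) with PR > 3.

## 6. Eye-trace processing

Saccades are inter-frame steps > 1° of visual angle. The step, a ±1-frame
guard, and a 0.5 s post-saccadic window are removed and gap-filled by
linear interpolation (uniform sampling is required by the filters and
FFT). The post-saccadic window exists because the glissadic re-centering
that follows a step otherwise leaks broadband energy into the 0.25 Hz band
and inflates the variance of per-animal phase estimates roughly two-fold.
Detection repeats until no supra-threshold step remains, making the
operation idempotent. Drift removal is a zero-phase 4th-order Butterworth
bandpass, 100–500 mHz: 0.25 Hz passes with gain > 0.999, content below
0.05 Hz is attenuated > 100×.

Amplitude is the mean per-cycle maximum minus mean per-cycle minimum
(per-cycle rather than global extrema — the whole-window alternative is
noise-dominated). Relative gain divides each test's amplitude by the first
test of the first session; the default spaced-training schedule has four
15-min sessions at 1 h intervals on day 1 (early/late 3-min eye windows,
5-min fluorescence windows) plus 2-min probes on days 2 and 5 — ten tests.
Gain–PR correlation is Pearson's r, either on group means per test or per
animal (day-5 gain normalized to late session 4 against that window's PR).

## 7. Synthetic generators

All generators draw from one seeded `numpy` Generator; identical arguments
and seed give bit-identical outputs, and the stored ground truth suffices
to rebuild the noiseless signal.

- **Events**: intervals, peaks and half-widths are normal deviates
  truncated at zero (only means ± SD and unimodal cumulative curves are
  known; a truncated normal is the minimal assumption). Defaults:
  15.8 ± 4.8 s, 10.4 ± 3.7 %, 1.6 ± 0.4 s. Each transient rises linearly
  over one sample interval (0.2 s — "near-instantaneous" against 15.8 s
  intervals) and decays with τ = (halfwidth − rise/2)/ln 2, which makes
  the continuous-time FWHM equal the drawn half-width *exactly*; a truly
  discontinuous rise would make any interpolating estimator read the left
  half-crossing half a sample early, a +6 % half-width artifact that is a
  property of the discretization, not of the physiology being emulated.
  Onsets snap to the sample grid so drawn peaks are realized at a sample.
- **Photometry pairs**: channel 1 is baseline × (1 + locked modulation) ×
  exponential fade + noise (defaults: 3 % locked amplitude, τ = 600 s
  fade, 1 % noise); channel 2 is the modulation inverted (mirror) and/or
  delayed, with its own fade (1.2×τ) and independent noise. Intermittent
  locking alternates locked/unlocked epochs with exponential durations
  (80 s mean epoch pair; `lock_fraction` sets the duty cycle). True phase
  = 180°·mirror + lag/T·360°. Companion-channel lag defaults encode the
  two shadow-channel models: 0.0489 s (near-pure mirror, 184.4°) and
  0.7433 s (lagged autofluorescence, 246.9°).
- **Vessel stacks**: a vertical band with projected-cylinder cross-section
  on a dim background; the profile scales with the chord length through
  the lumen, so the peak brightens as the vessel dilates — this coupling
  is what the diameter/peak-intensity correlation check exercises.
  Default true diameter 45.7 µm at 1 µm pixels, 5 % diameter oscillation
  at 0.1 Hz (spontaneous vasomotion band), 1 % pixel noise.
- **Eye traces**: gain × delayed stimulus + slow sinusoidal drift
  (0.003–0.01 Hz, 2°) + Gaussian noise (0.1°) + Poisson saccades
  (6/min, steps 1.5–4°, exponential re-centering with τ = 0.5 s).
  Defaults: gain 0.5, lag 2.3°.

Not emulated: heartbeat (~10 Hz) pulsation, respiration, motion artifacts,
pupil dynamics, harmonics of the locked oscillation, spatial heterogeneity
of entrainment within a field (except via the PR-map test constructions),
and correlated (1/f) sensor noise. Passing recovery tests therefore shows
the estimators are correct under the stated signal model, not that the
model exhausts real recordings.

## 8. Problem sizes and tolerances

The recovery checks run at desk scale: 20 × 10-min event sessions,
13/28 × 5-min photometry pairs, 5 × 5-min eye traces, 5 × 20 s vessel
stacks, one 15-min entrained trace. Recovery tolerances: event statistics
within 5 % of their generating means; pair phases within one lag quantum
(18°) plus 2 SE; eye lag within 2 SE over five animals; diameter within
one pixel after √0.99 correction. The full test suite and the acceptance
script each run in seconds.

## 9. Known limitations

- Single vessel per stack, no segmentation, tracing or registration.
- The FW10M ↔ diameter mapping assumes the projected-cylinder profile; for
  vessels with significant wall signal or out-of-focus blur the index
  remains monotone in diameter but the √0.99 correction is nominal.
- Cross-correlation phase is quantized to the sample grid unless parabolic
  refinement is enabled.
- The event detector's threshold rule assumes noise is broadband relative
  to the transients; strongly correlated noise would require a manual
  threshold.
- Group-level inferential statistics beyond Pearson correlations are out
  of scope.
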