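# Methods

This note records the models, conventions and numerical choices behind
`cardiospec`, and what the synthetic-data generator does and does not
emulate.

## The measurement being modelled

An isolated beating heart viewed in brightfield darkens a ring of pixels at
its border as the tissue contracts and dilates.  The mean intensity of a
border ROI therefore oscillates at the beat rate, superimposed on slow
additive trends (focus drift, evaporation, lamp warm-up) and camera noise.
Heartbeat movies are sampled at 5 Hz; Ca²⁺-reporter recordings at 0.5 Hz.
A screening session consists of a baseline control reading, a compound
addition, and a buffer wash that continues until the recording again
resembles the baseline, at which point the next compound can be tested.

## Synthetic dish generator

The generator exists so that every downstream stage has exact ground truth;
it is first-class, tested code, not a fixture.

**Geometry.**  Each heart is an ellipse of dark tissue (interior 400 a.u.)
on a bright field (background 1000 a.u.).  Contraction scales the semi-axes
by `1 + amplitude_frac · s(t)`.  Rendering uses pixel-center membership only
(no sub-pixel area weighting); a heart must fit inside the frame at maximal
dilation or a geometry error is raised.  Rasterization quantization makes a
single border pixel flip worth a fraction of an intensity unit in the ROI
mean; the default ROI radius of ~1.1 × the semi-axis straddles the border
and sees ~tens of pixels flip per beat.

**Beat timing.**  Inter-beat intervals are gamma-distributed with mean
`1/beat_freq_hz` and coefficient of variation `ibi_jitter_cv` (positive
support, tunable irregularity).  The first beat falls at half a mean period;
scheduled beats are omitted independently with `skip_prob`; `arrest_after_s`
truncates the schedule.  With zero jitter and skips the schedule is exactly
periodic.

**Waveform.**  The default contraction waveform is a raised-cosine pulse of
duty cycle 0.3 centered on each beat — brightfield beats are pulse-like, and
pulse trains exercise spectral harmonics the way real recordings do.  A pure
sinusoid (which ignores the stochastic schedule) is provided for analytic
tests.

**Defaults as study conditions.**  5 Hz movie sampling and 0.5 Hz Ca²⁺
sampling; 3–5 hearts per dish; beat rates in 0.5–2.5 Hz (1 Hz default);
`amplitude_frac` 0.15; baseline `ibi_jitter_cv` 0.05 (a healthy heart shows
a few percent cycle-to-cycle variation); recording duration 120 s per
reading (long enough for ≥60 beats at the slowest rate while keeping a
screen at minutes per compound; no canonical value exists).  Compound
concentration metadata defaults to 10 μM, the typical screening dose.

**Noise and SNR.**  Noise is additive white Gaussian only (Poisson/photon
statistics are out of scope).  SNR is defined as the RMS of the beat
component about its mean divided by the noise SD; for a raised-cosine pulse
train of height *h* and duty *d*, signal variance is *h²(3d/8 − d²/4)*.
`noise_sd_for_snr` inverts this.  Statistical guarantees (beat recall,
classifier sensitivity) are calibrated at SNR 5.  Note the arrest rule
(band power < 5% of baseline) implicitly requires SNR ≳ 4.4, since the
noise floor itself contributes `1/(1+SNR²)` of baseline band power.

**Sessions.**  `simulate_session` walks beat times through ordered
baseline/compound/wash segments; a compound segment swaps in an override
parameter set, and a wash relaxes frequency, amplitude, jitter and skip
probability back to baseline as `x(t) = x_base + (x_drug − x_base)·e^{−t/τ}`.
A persistent arrest is expressed with an explicit wash override.  Two render
modes exist: `movie` (full optical model, concatenated frames) and `trace`
(the border-ROI trace emulated directly as
`500 + 200·amplitude_frac·s(t) + drift + noise`), which is used for
statistical calibration at scale.

**Ca²⁺ traces.**  Baseline F₀ plus spontaneous transients arriving as a
Poisson process (default 0.02 events/s), each with instant rise and
exponential decay (τ = 20 s), amplitudes specified as ΔF/F₀ fractions;
an optional compound-evoked transient (default ΔF/F₀ = 1.2, τ = 60 s) at the
addition time.  Event onsets snap to the sample grid, so a noise-free
transient peaks exactly at `F₀(1 + A)` on its onset sample.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: photorealistic morphology, optical PSF and motion
blur, photon (Poisson) noise, photobleaching nonlinearity, heart drift or
rotation within the dish, mechanical coupling between hearts, and dye
ratiometrics.  Claims about classifier sensitivity/specificity are claims
about this noise model at the stated SNR.

## Detrending

Ordinary least squares on a polynomial in time (default degree 2 — enough
for slow focus drift without absorbing sub-0.2 Hz physiology; tunable via
`--degree`).  Time is centered at the trace midpoint before fitting for
conditioning; coefficients are stored in the centered basis and converted
for display.  The residual is z-scored (population SD) so spectra are
comparable across hearts; the *unnormalized* residual and its variance are
kept alongside, because z-scoring deliberately destroys amplitude
information.  A residual whose RMS is below 1e-9 of the signal scale is
flagged flat and returned as zeros rather than dividing by zero.
Consequences, all tested: adding any polynomial of degree ≤ d to a trace
leaves the output unchanged to 1e-8; detrending is idempotent; constant
shifts never matter.

## Spectra

One-sided periodogram with `P_k = c_k |X_k|²/N²` (c_k = 1 at DC and Nyquist,
2 elsewhere), so Σ P_k equals the mean square of the analyzed signal — an
exactly testable Parseval identity, verified elementwise against a
brute-force O(N²) DFT.  The Hann window, when requested, is applied with a
`1/√(mean w²)` power correction so the identity continues to hold for the
windowed signal; analytic tests use the rectangular window.

**Dominant frequency** is the maximal-power bin at `f ≥ f_min` (default
0.2 Hz, suppressing residual drift leakage), with near-ties (1e-9 relative)
breaking toward the lower frequency.  A peak must clear a robust noise
floor, `median + K·MAD` of the DC-excluded spectrum.  K scales with the bin
count n as `(ln(n/0.05) − ln 2)/asinh(½)` (never below 10): for
exponentially distributed white-noise bins this puts the family-wise
false-peak probability at ~5% regardless of spectrum length, which a fixed
multiplier cannot do (at n = 300 a fixed K = 10 flags a false peak two times
in three).

## Effect classification

`compare_spectra` reduces a baseline/treated pair to:

* **jsd** — Jensen–Shannon divergence (base 2, bounded [0,1]) between the
  unit-normalized, DC-excluded spectra after power-conserving re-binning
  onto a common grid no finer than 0.1 Hz.  The coarse grid serves two
  purposes: spectra of different lengths become comparable, and the argmax
  of a jitter-broadened peak stops hopping native bins.  0.1 Hz ≈ 10% of a
  1 Hz beat — differences below that are within a healthy heart's natural
  wobble.
* **delta_f_dom** — dominant-frequency difference on that grid (None if
  either spectrum has no peak).
* **band_power_ratio** — treated/baseline unnormalized residual variance.
* **null_jsd_q95** — the 95th percentile of JSD between two disjoint
  treated-length segments of the circularly-shifted baseline trace (200
  resamples): the spectral wobble intrinsic to *this* heart.  The effective
  shape threshold is `max(null_q95, 0.1 bits)`; the fixed floor is a
  minimum meaningful effect size.  Under simulation at SNR 5 the separation
  is wide — vehicle-control jsd tops out near 0.05 bits while genuine rhythm
  disruptions start near 0.2 — so the floor only guards against an
  under-dispersed null on unusually clean baselines.

Decision order (first match wins): arrest → frequency_shift →
amplitude_change → irregularity → no_effect, with the rules given in the
README.  "Spectra identical to baseline" is thus operationalized as: jsd
below threshold, dominant frequency within one bin, band power within
[0.5, 2].  All three thresholds are overridable (`--jsd-thresh` etc.).

Measured behaviour at the default settings (100 seeded runs per family,
SNR 5, 120 s segments, recomputed by `scripts/acceptance.py`): specificity
and each sensitivity ≥ 97%.

## Beat and Ca²⁺ detection

Beats are local maxima of the detrended trace with prominence ≥ 4 × MAD,
separated by at least half the expected period (hint from the spectrum).
If the MAD is zero — a quiescent, noise-free trace — the scale falls back
to 2.5e-4 of the signal range so clean pulses are never thresholded away.
The trace is padded with its minimum at both ends so a beat on the first or
last sample remains detectable.  Beat amplitude is the peak prominence on
the unnormalized residual.

Ca²⁺ events are called on ΔF/F₀ with F₀ a running low percentile (default
10th, 60 s centered window).  One event per supra-threshold excursion
(default threshold 0.2), with two split rules for transients stacking on a
predecessor's decay tail: a one-sample jump ≥ threshold (the kernel rises
instantly), or a re-rise ≥ threshold above the valley after falling ≥
threshold from the peak.  Without splitting, ~30% of Poisson-arriving
transients at the default rate would merge and recall would be capped near
0.7.  Event amplitude is the peak above the event's own starting level, so
an isolated noise-free transient of amplitude A is recovered exactly.
Calling is scale-invariant (ΔF/F₀ is ratio-based).

## Screening sessions

Sessions are segmented at event-log times; the flowchart ordering is
validated (a control reading must precede the first compound; washes follow
compounds).  The first 2 s of compound and wash segments are discarded — a
pipetted compound needs a moment to mix, and a hard slice at the event time
would catch the transition (including a beat pulse straddling the
boundary).

**Washout recovery** slides a 30 s window (step 10 s) over the wash.  Each
window is compared not against the full-length baseline spectrum but
against a *windowed baseline reference*: the mean spectrum of equal-length
baseline windows, with a null threshold from circularly-shifted baseline
windows.  A short window carries window-length leakage and estimator noise
that a long-baseline spectrum does not; comparing like with like removes a
systematic jsd offset (~0.15 bits) that otherwise delays or destabilizes
recovery detection.  Recovery is declared at the first of two consecutive
`no_effect` windows (hysteresis prevents flicker).  The 30 s default gives
≥ 15 beats per window at 0.5 Hz beating.

For an exponentially relaxing frequency offset Δf·e^{−t/τ}, the window's
dominant coarse bin realigns with baseline when the mid-window offset drops
below half a classification bin ≈ the window's own resolution, giving the
closed-form recovery time `τ·ln(Δf·T_win) − T_win/2`.  Detected times match
this within one window and are monotone in τ (tested at τ = 10, 30, 60 s,
averaged over the 5 hearts of a dish).

Per-heart analysis only: the 3–5 hearts of a dish are never pooled into one
spectrum; reports aggregate by listing.  Vehicle-control segments (compound
name equal to the solvent label) are flagged as controls and expected
`no_effect`.

## Determinism and formats

All randomness flows from a single integer seed through
`numpy.random.SeedSequence.spawn` (one stream per heart plus one for
noise); identical configs give bit-identical movies, traces, reports.
Writers are byte-deterministic: JSON with sorted keys, trace tables with
`%.17g` floats (read back with round-trip float parsing), movies as 16-bit
grayscale multi-page TIFF clipped to [0, 65535].  The frame rate is never
stored in TIFF tags — it is an explicit argument everywhere, as acquisition
software keeps it out of band.  Pixel coordinates are 0-based (row, col)
with centers at integer coordinates.  The ImageJ binary `.roi` format is
not parsed; ROI sets are JSON.

## Known limitations

* The classifier is per-heart and single-dose; no pooling across hearts,
  replicate statistics, or dose–response fitting.
* Dominant-frequency logic assumes beats below Nyquist (2.5 Hz at 5 Hz
  sampling); faster beating aliases and is not flagged.
* Ca²⁺ analysis is single-channel intensity; ratiometric (340/380 nm)
  acquisition is out of scope.
* The noise-floor and jsd-floor calibrations are exact for the generator's
  white-noise model; strongly colored noise (e.g. flow pulsation) would
  require re-calibration.
* Welch averaging, multitaper and time–frequency methods are deliberately
  absent; the periodogram convention is fixed so its invariants are exact.
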