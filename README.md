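# cardiospec

Analysis toolkit for **ex vivo beating-heart drug screens**: isolated adult
hearts (3–5 per dish, e.g. zebrafish) are kept alive in a glass-bottom Petri
dish, imaged by brightfield time-lapse at 5 Hz (or by a Ca²⁺-sensitive dye at
0.5 Hz), and challenged with small molecules.  A compound is pipetted in, its
effect on beating is recorded, the dish is washed, and the next compound is
tested once the recording again resembles the initial control reading.

`cardiospec` turns those recordings into quantitative per-heart verdicts.  It
is aimed at labs running cardiotoxicity screens (hERG-type liabilities,
contractility inhibitors) who need a reproducible, scriptable replacement for
by-eye spectrum comparison — and it ships a fully seeded synthetic-dish
generator, so every stage of the pipeline is testable against known ground
truth without any microscope.

## Pipeline

1. **ROI traces** — regions of interest drawn around each heart border are
   rasterized (pixel-center membership) and reduced to per-frame mean
   intensities: movement of the beating border modulates the mean.
2. **Detrending** — each trace *y(t)* is fit with an ordinary least-squares
   polynomial (default degree 2) in time to remove focus drift and slow
   trends; the residual is z-scored.  The unnormalized residual variance is
   kept as the trace's *band power* (its amplitude information).
3. **Spectra** — the one-sided periodogram with the convention
   *P_k = c_k |X_k|² / N²* (c_k = 1 at DC/Nyquist, 2 elsewhere), so that
   Σ_k P_k equals the mean square of the analyzed signal (Parseval,
   exactly testable).  The beat rate is 60 × the dominant frequency.
4. **Effect classification** — a treated spectrum is compared with the same
   heart's baseline through three statistics:
   * `jsd` — Jensen–Shannon divergence (base 2) between unit-normalized,
     DC-excluded spectra, re-binned onto a common 0.1 Hz grid;
   * `delta_f_dom` — dominant-frequency shift;
   * `band_power_ratio` — treated/baseline residual variance.
   The decision order is **arrest** (no spectral peak and band power < 5% of
   baseline) → **frequency_shift** (peak moved by more than one bin and the
   shape changed) → **amplitude_change** (power ratio outside [0.5, 2]) →
   **irregularity** (shape changed without a peak move, e.g. broadening) →
   **no_effect**.  The shape-change threshold is data-driven: the 95th
   percentile of JSD between circularly-shifted splits of the baseline
   itself, floored at a minimum meaningful effect size of 0.1 bits.
5. **Screening sessions** — recordings are segmented at event-log times into
   baseline / compound / wash; washout recovery is declared when two
   consecutive 30 s windows of the wash classify `no_effect` against a
   windowed baseline reference.
6. **Time-domain metrics** — beat times (MAD-scaled peak prominence), beat
   rate, inter-beat-interval CV, and ΔF/F₀ Ca²⁺ transient calls with
   compound-response quantification.

## Worked example

Simulate a dish of three hearts beating at 1 Hz, add a hERG-blocker-like
compound (beat rate 1.6 Hz, increased irregularity) at 120 s, wash at 240 s
with a 30 s recovery time constant, and evaluate each heart:

```python
import dataclasses
from cardiospec import (ContractionModel, SegmentSpec, default_dish,
                        simulate_session, segment_session, evaluate_compound,
                        noise_sd_for_snr)

baseline = ContractionModel(beat_freq_hz=1.0, amplitude_frac=0.15, ibi_jitter_cv=0.05)
clofilium_like = dataclasses.replace(baseline, beat_freq_hz=1.6, ibi_jitter_cv=0.12)

dish = default_dish(n_hearts=3, seed=11, contraction=baseline)
protocol = [
    SegmentSpec("baseline", 120.0),
    SegmentSpec("compound", 120.0, override=clofilium_like,
                compound_name="clofilium", concentration_um=10.0),
    SegmentSpec("wash", 300.0, wash_tau_s=30.0),
]
sim = simulate_session(dish, protocol, render="trace",
                       trace_noise_sd=noise_sd_for_snr(baseline, 5.0))
session = segment_session(sim.table, sim.events)

for roi in session.roi_ids:
    rep = evaluate_compound(session, roi)
    c = rep.comparison
    fd = "no peak" if c.f_dom_treated is None else f"{c.f_dom_treated:.2f} Hz"
    rec = rep.recovery.recovery_time_s if rep.recovery else None
    print(f"{roi}: {rep.classification:16s} "
          f"f_dom {c.f_dom_baseline:.2f} Hz -> {fd}  "
          f"jsd {c.jsd:.3f} (null q95 {c.null_jsd_q95:.3f})  "
          f"power ratio {c.band_power_ratio:.2f}  "
          f"recovered after {rec:.0f} s of wash")
```

prints

```
heart1: frequency_shift  f_dom 1.00 Hz -> 1.60 Hz  jsd 0.571 (null q95 0.059)  power ratio 1.35  recovered after 82 s of wash
heart2: frequency_shift  f_dom 1.00 Hz -> 1.60 Hz  jsd 0.529 (null q95 0.056)  power ratio 1.40  recovered after 72 s of wash
heart3: frequency_shift  f_dom 1.00 Hz -> 1.60 Hz  jsd 0.499 (null q95 0.103)  power ratio 1.23  recovered after 92 s of wash
```

Each heart's dominant frequency moved from 1.00 to 1.60 Hz; the spectral
shape change (jsd ≈ 0.5 bits) dwarfs the heart's own baseline wobble
(null q95 ≈ 0.06–0.10), so the verdict is `frequency_shift`.  Beating
returned to a state indistinguishable from baseline 72–92 s into the wash —
consistent with the exponential washout: the window's dominant bin realigns
once the frequency offset decays below the window resolution, at
τ·ln(Δf·T_win) − T_win/2 ≈ 66 s for τ = 30 s.

The same analyses run from the shell on recorded data:

```bash
cardiospec simulate --config dish.json --out dish.tiff      # synthetic data
cardiospec extract  --movie dish.tiff --fs 5 --rois rois.json --out traces.dat
cardiospec analyze  --trace traces.dat --roi heart1 --mode beats --out beats.json
cardiospec compare  --baseline base.dat --treated drug.dat --out report.json
cardiospec screen   --config screen.json --out report.json  # full session
```

## Layout

```
src/cardiospec/
  synthetic_dish.py   seeded generator: dishes, movies, Ca2+ traces, sessions
  movie_io.py         TIFF / ROI-JSON / .dat|.csv trace tables / JSON reports
  roi_trace.py        ROI rasterization + mean-intensity extraction
  preprocess.py       polynomial detrending + normalization
  spectral.py         periodogram, dominant frequency, effect classifier
  beat_calcium.py     beat detection, rhythm metrics, Ca2+ events
  screening.py        session segmentation, washout recovery, batch driver
  cli.py              `cardiospec` command-line interface
docs/methods.md       model, parameter and design notes
```
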