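"""Frequency-domain analysis of detrended beat traces.

The periodogram convention is fixed so that Parseval's identity is exactly
testable: with ``X_k`` the DFT of the analyzed signal ``y`` of length ``N``,

    P_k = |X_k|^2 / N^2          for k = 0 and k = N/2 (N even),
    P_k = 2 |X_k|^2 / N^2        otherwise,

so that ``sum_k P_k == mean(y^2)``.  With the Hann window the signal is
rescaled by ``1/sqrt(mean(w^2))`` before transforming, which preserves the
identity for the windowed signal.  A bin-aligned unit sinusoid therefore puts
power 1/2 (its mean square) in a single interior bin.

Compound effects are decided by comparing the treated spectrum against the
baseline spectrum of the same heart:

* ``jsd`` — Jensen-Shannon divergence (base 2) between the unit-normalized,
  DC-excluded spectra, a bounded shape-change statistic;
* ``delta_f_dom`` — shift of the dominant (maximal-power) frequency;
* ``band_power_ratio`` — treated / baseline unnormalized residual variance,
  the amplitude statistic (z-scored spectra carry no amplitude);
* ``null_jsd_q95`` — a data-driven threshold: the 95th percentile of JSD
  between two disjoint segments of the circularly-shifted baseline trace,
  which captures how much the spectrum of *this* heart wobbles on its own.

Both spectra are re-binned by power-conserving bin-sum onto a common
classification grid no finer than ``CLASSIFY_BIN_HZ`` (default 0.1 Hz) before
jsd/dominant-frequency comparison: beat-rate wobble of a healthy heart is a
few percent, so differences below ~0.1 Hz at ~1 Hz beating are within natural
variation, and the coarse grid keeps the argmax of a jitter-broadened peak
from hopping bins.

Classification decision order (first match wins):

1. ``arrest`` — treated spectrum has no peak above the noise floor and its
   band power fell below 5% of baseline;
2. ``frequency_shift`` — dominant frequency moved by more than one
   classification bin *and* the shape changed (jsd above the null threshold);
3. ``amplitude_change`` — band-power ratio outside [0.5, 2.0];
4. ``irregularity`` — shape changed (jsd above threshold) without a
   dominant-frequency move, e.g. peak broadening;
5. ``no_effect`` — spectra indistinguishable from natural variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .errors import IncompatibleSpectraError, TooShortError
from .preprocess import DetrendedTrace

__all__ = [
    "PowerSpectrum",
    "SpectralComparison",
    "power_spectrum",
    "dominant_frequency",
    "compare_spectra",
    "classify_effect",
    "CLASSIFY_BIN_HZ",
    "DEFAULT_F_MIN_HZ",
]

DEFAULT_F_MIN_HZ = 0.2
CLASSIFY_BIN_HZ = 0.1
NOISE_FLOOR_MADS = 10.0
ARREST_POWER_FRAC = 0.05
AMPLITUDE_RATIO_BAND = (0.5, 2.0)
N_NULL_RESAMPLES = 200
#: minimum meaningful shape change, bits.  The data-driven null threshold is
#: never taken below this: JSD fluctuations of a stable beat spectrum sit far
#: below it while genuine rhythm disruptions sit far above, so it guards
#: against an under-dispersed null on particularly clean baselines.
JSD_MIN_EFFECT = 0.1


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided periodogram under the package's Parseval convention."""

    frequencies: np.ndarray  # hertz, ascending, k*fs/N for k = 0..floor(N/2)
    power: np.ndarray
    fs_hz: float
    n_samples: int
    window: str
    total_band_power: float  # unnormalized residual variance (amplitude info)
    analyzed_mean_square: float  # mean square of the (windowed) analysis signal

    @property
    def df_hz(self) -> float:
        """Native frequency resolution fs/N."""
        return self.fs_hz / self.n_samples


@dataclass(frozen=True)
class SpectralComparison:
    """Baseline-vs-treated comparison statistics and verdict."""

    jsd: float
    delta_f_dom: float | None  # None when either spectrum has no peak
    f_dom_baseline: float | None
    f_dom_treated: float | None
    band_power_ratio: float
    null_jsd_q95: float
    bin_hz: float  # classification grid width; the "one bin" tolerance
    treated_no_peak: bool
    classification: str


def _periodogram(values: np.ndarray, fs_hz: float, window: str) -> tuple[np.ndarray, np.ndarray, float]:
    y = np.asarray(values, dtype=float)
    n = y.size
    if window == "hann":
        w = windows.hann(n, sym=False)
        y = y * w / np.sqrt(np.mean(w**2))
    elif window != "rect":
        raise ValueError(f"unknown window {window!r}")
    x = np.fft.rfft(y)
    p = np.abs(x) ** 2 / n**2
    p[1:] *= 2.0
    if n % 2 == 0:
        p[-1] /= 2.0
    freqs = np.arange(p.size) * (fs_hz / n)
    return freqs, p, float(np.mean(y**2))


def power_spectrum(trace: DetrendedTrace, window: str = "rect") -> PowerSpectrum:
    """One-sided periodogram of a detrended trace.

    Parameters
    ----------
    trace
        Output of :func:`cardiospec.preprocess.detrend_normalize`.
    window
        ``"rect"`` (default, exact for analytic tests) or ``"hann"``
        (preferred for real recordings; sidelobe suppression).
    """
    n = len(trace)
    if n < 8:
        raise TooShortError(f"need >= 8 samples for a spectrum, got {n}")
    freqs, p, msq = _periodogram(trace.values, trace.fs_hz, window)
    return PowerSpectrum(
        frequencies=freqs,
        power=p,
        fs_hz=trace.fs_hz,
        n_samples=n,
        window=window,
        total_band_power=trace.residual_variance,
        analyzed_mean_square=msq,
    )


def _noise_floor(power: np.ndarray) -> float:
    """Robust peak floor: median + K*MAD of the DC-excluded spectrum.

    K scales with the number of bins so that a pure white-noise spectrum
    (exponentially distributed bins; median = ln2 mu, MAD = asinh(1/2) mu)
    exceeds the floor anywhere with only ~5% probability: the per-bin
    threshold mu*ln(n/0.05) expressed in robust units.  K never drops below
    ``NOISE_FLOOR_MADS``.
    """
    body = power[1:]
    n = body.size
    med = float(np.median(body))
    mad = float(np.median(np.abs(body - med)))
    k = max(NOISE_FLOOR_MADS, (np.log(n / 0.05) - np.log(2)) / np.arcsinh(0.5))
    return med + k * mad


def dominant_frequency(
    spec: PowerSpectrum, f_min: float = DEFAULT_F_MIN_HZ
) -> float | None:
    """Frequency of the maximal-power bin at f >= f_min, or None (no peak).

    The peak must exceed a robust noise floor (median + 10 MAD of the
    DC-excluded spectrum); ties break toward the lower frequency.
    """
    if not f_min < spec.fs_hz / 2:
        raise ValueError(f"f_min {f_min} must be below Nyquist {spec.fs_hz / 2}")
    return _dominant_from_arrays(spec.frequencies, spec.power, f_min)


def _dominant_from_arrays(
    freqs: np.ndarray, power: np.ndarray, f_min: float
) -> float | None:
    sel = freqs >= f_min
    if not np.any(sel):
        return None
    floor = _noise_floor(power)
    band = power[sel]
    peak = float(band.max())
    if peak <= floor or peak == 0.0:
        return None
    # near-ties (within 1e-9 relative) break toward the lower frequency
    k = int(np.flatnonzero(band >= peak * (1.0 - 1e-9))[0])
    return float(freqs[sel][k])


def _rebin(freqs: np.ndarray, power: np.ndarray, bin_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Power-conserving bin-sum onto a grid of width bin_hz.

    Native bin k at frequency f maps to coarse index round(f / bin_hz); the
    coarse bin's representative frequency is its center j*bin_hz.
    """
    idx = np.round(freqs / bin_hz).astype(int)
    out = np.bincount(idx, weights=power)
    return np.arange(out.size) * bin_hz, out


def _jsd_bits(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence, base 2, between nonnegative vectors."""
    ps, qs = p.sum(), q.sum()
    if ps == 0.0 and qs == 0.0:
        return 0.0
    if ps == 0.0 or qs == 0.0:
        return 1.0
    p = p / ps
    q = q / qs
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_p = np.where(p > 0, p * np.log2(p / m), 0.0)
        kl_q = np.where(q > 0, q * np.log2(q / m), 0.0)
    return float(np.clip(0.5 * kl_p.sum() + 0.5 * kl_q.sum(), 0.0, 1.0))


def _null_jsd_q95(
    baseline: DetrendedTrace,
    seg_len: int,
    bin_hz: float,
    window: str,
    n_resamples: int,
    seed: int,
) -> float:
    """95th percentile of JSD between two disjoint segments of the baseline.

    The baseline trace is circularly shifted ``n_resamples`` times; each
    shift yields two non-overlapping segments of ``seg_len`` samples whose
    spectra (same convention, re-binned to the classification grid) are
    compared.  This measures the spectral wobble intrinsic to the heart.
    """
    x = np.asarray(baseline.values, dtype=float)
    n = x.size
    half = n // 2
    seg_len = int(min(seg_len, half))
    rng = np.random.default_rng(seed)
    shifts = rng.integers(0, n, size=n_resamples)
    segs_a = np.empty((n_resamples, seg_len))
    segs_b = np.empty((n_resamples, seg_len))
    for i, s in enumerate(shifts):
        xs = np.roll(x, int(s))
        segs_a[i] = xs[:seg_len]
        segs_b[i] = xs[half : half + seg_len]
    segs_a -= segs_a.mean(axis=1, keepdims=True)
    segs_b -= segs_b.mean(axis=1, keepdims=True)
    if window == "hann":
        w = windows.hann(seg_len, sym=False)
        segs_a = segs_a * w
        segs_b = segs_b * w
    pa = np.abs(np.fft.rfft(segs_a, axis=1)) ** 2
    pb = np.abs(np.fft.rfft(segs_b, axis=1)) ** 2
    freqs = np.arange(pa.shape[1]) * (baseline.fs_hz / seg_len)
    idx = np.round(freqs / bin_hz).astype(int)
    jsds = np.empty(n_resamples)
    for i in range(n_resamples):
        ca = np.bincount(idx, weights=pa[i])
        cb = np.bincount(idx, weights=pb[i])
        jsds[i] = _jsd_bits(ca[1:], cb[1:])
    return float(np.quantile(jsds, 0.95))


def compare_spectra(
    baseline: PowerSpectrum,
    treated: PowerSpectrum,
    baseline_trace: DetrendedTrace,
    f_min: float = DEFAULT_F_MIN_HZ,
    jsd_threshold: float | None = None,
    classify_bin_hz: float = CLASSIFY_BIN_HZ,
    n_resamples: int = N_NULL_RESAMPLES,
    seed: int = 0,
) -> SpectralComparison:
    """Compare a treated spectrum against the baseline of the same heart.

    Spectra of unequal resolution are re-binned by bin-sum onto the coarser
    grid (never finer than ``classify_bin_hz``) before the shape and
    dominant-frequency comparison; the band-power ratio uses the
    unnormalized residual variances carried on the spectra.

    ``jsd_threshold`` overrides the data-driven null (the 95th percentile of
    within-baseline JSD under circular-shift resampling).
    """
    if not np.isclose(baseline.fs_hz, treated.fs_hz, rtol=1e-9):
        raise IncompatibleSpectraError(
            f"sampling rates differ: {baseline.fs_hz} vs {treated.fs_hz} Hz"
        )
    bin_hz = max(baseline.df_hz, treated.df_hz, classify_bin_hz)
    fb, pb = _rebin(baseline.frequencies, baseline.power, bin_hz)
    ft, pt = _rebin(treated.frequencies, treated.power, bin_hz)
    m = min(pb.size, pt.size)
    fb, pb, pt = fb[:m], pb[:m], pt[:m]
    jsd = _jsd_bits(pb[1:], pt[1:])
    f_dom_b = _dominant_from_arrays(fb, pb, f_min)
    f_dom_t = _dominant_from_arrays(fb, pt, f_min)
    delta = None if (f_dom_b is None or f_dom_t is None) else f_dom_t - f_dom_b
    if baseline.total_band_power > 0:
        ratio = treated.total_band_power / baseline.total_band_power
    else:
        ratio = np.inf if treated.total_band_power > 0 else 1.0
    if jsd_threshold is None:
        q95 = _null_jsd_q95(
            baseline_trace, treated.n_samples, bin_hz, treated.window, n_resamples, seed
        )
    else:
        q95 = float(jsd_threshold)
    label = classify_effect(
        jsd=jsd,
        delta_f_dom=delta,
        band_power_ratio=ratio,
        null_jsd_q95=q95,
        bin_hz=bin_hz,
        treated_no_peak=f_dom_t is None,
        # an explicit user threshold is taken literally, without the floor
        jsd_min_effect=0.0 if jsd_threshold is not None else JSD_MIN_EFFECT,
    )
    return SpectralComparison(
        jsd=jsd,
        delta_f_dom=delta,
        f_dom_baseline=f_dom_b,
        f_dom_treated=f_dom_t,
        band_power_ratio=ratio,
        null_jsd_q95=q95,
        bin_hz=bin_hz,
        treated_no_peak=f_dom_t is None,
        classification=label,
    )


def classify_effect(
    jsd: float,
    delta_f_dom: float | None,
    band_power_ratio: float,
    null_jsd_q95: float,
    bin_hz: float,
    treated_no_peak: bool,
    jsd_min_effect: float = JSD_MIN_EFFECT,
) -> str:
    """Apply the decision table; see the module docstring for the order.

    The effective shape-change threshold is ``max(null_jsd_q95,
    jsd_min_effect)``: the null captures this heart's own spectral wobble,
    the floor enforces a minimum meaningful effect size.
    """
    lo, hi = AMPLITUDE_RATIO_BAND
    jsd_thresh = max(null_jsd_q95, jsd_min_effect)
    if treated_no_peak and band_power_ratio < ARREST_POWER_FRAC:
        return "arrest"
    if (
        delta_f_dom is not None
        and abs(delta_f_dom) > bin_hz * (1 + 1e-9)
        and jsd > jsd_thresh
    ):
        return "frequency_shift"
    if not lo <= band_power_ratio <= hi:
        return "amplitude_change"
    if jsd > jsd_thresh:
        return "irregularity"
    return "no_effect"
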