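"""Time-domain readouts: beat detection, rhythm metrics, Ca2+ events.

Beats are local maxima of the detrended trace with a prominence of at least
``min_prominence_mads`` times the trace's median absolute deviation,
separated by at least half the expected beat period (the period hint comes
from the spectral dominant frequency when not supplied).  Beat amplitude is
measured on the detrended *unnormalized* residual — z-scoring destroys
amplitude information.

Ca2+ transients are called on Delta-F/F0: F0 is a running low percentile of
the raw fluorescence (window 60 s), and one event is emitted per contiguous
supra-threshold run of (F - F0)/F0, with the run maximum as its amplitude.
The calls are invariant to multiplying the trace by any positive constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import percentile_filter
from scipy.signal import find_peaks

from .errors import DataError, InsufficientDataError, InvalidParameterError
from .errors import TruncatedWindowWarning
from .movie_io import IntensityTrace
from .preprocess import DetrendedTrace
from .spectral import DEFAULT_F_MIN_HZ, dominant_frequency, power_spectrum

__all__ = [
    "BeatMetrics",
    "CalciumEvents",
    "detect_beats",
    "interbeat_stats",
    "detect_calcium_events",
    "compound_response",
]

DEFAULT_MIN_PROMINENCE_MADS = 4.0
DEFAULT_THRESHOLD_DFF = 0.2
DEFAULT_F0_PERCENTILE = 10.0
F0_WINDOW_S = 60.0


@dataclass(frozen=True)
class BeatMetrics:
    """Beat times and rhythm summary of one trace."""

    beat_times: np.ndarray
    mean_beat_amplitude: float  # on the unnormalized residual
    arrest_flag: bool
    ibi_mean_s: float | None = None
    ibi_cv: float | None = None

    @property
    def beat_count(self) -> int:
        return int(self.beat_times.size)

    @property
    def mean_rate_bpm(self) -> float | None:
        if self.beat_count < 2:
            return None
        span = self.beat_times[-1] - self.beat_times[0]
        return 60.0 * (self.beat_count - 1) / span


@dataclass(frozen=True)
class CalciumEvents:
    """Detected Ca2+ transients on a Delta-F/F0 scale."""

    onset_times: np.ndarray
    amplitudes_dff: np.ndarray
    f0_estimate: float
    fs_hz: float
    dff: np.ndarray  # full Delta-F/F0 trace, for response windows

    @property
    def n_events(self) -> int:
        return int(self.onset_times.size)


def detect_beats(
    trace: DetrendedTrace,
    min_prominence_mads: float = DEFAULT_MIN_PROMINENCE_MADS,
    f_hint_hz: float | None = None,
) -> BeatMetrics:
    """Find beats as prominent local maxima of a detrended trace.

    When ``f_hint_hz`` is absent the dominant spectral frequency supplies the
    refractory spacing; if the spectrum has no peak either, the trace is
    treated as arrested.
    """
    if not min_prominence_mads > 0:
        raise InvalidParameterError("min_prominence_mads must be > 0")
    x = np.asarray(trace.values, dtype=float)
    if trace.flat:
        return BeatMetrics(np.array([]), 0.0, True)
    mad = float(np.median(np.abs(x - np.median(x))))
    if mad == 0.0:
        # a zero MAD means the trace is quiescent between beats (noise-free
        # pulse train): fall back to a small fraction of the signal range so
        # clean pulses are never thresholded away
        mad = max(float(np.ptp(x)) * 2.5e-4, 1e-12)
    if f_hint_hz is None:
        f_hint_hz = dominant_frequency(power_spectrum(trace), DEFAULT_F_MIN_HZ)
        if f_hint_hz is None:
            return BeatMetrics(np.array([]), 0.0, True)
    distance = max(1, int(round(0.5 / f_hint_hz * trace.fs_hz)))
    # pad with the trace minimum so a beat landing on the first/last sample
    # is still a detectable local maximum
    xp = np.concatenate([[x.min()], x, [x.min()]])
    peaks, _ = find_peaks(
        xp, prominence=min_prominence_mads * mad, distance=distance
    )
    peaks = peaks - 1
    if peaks.size == 0:
        return BeatMetrics(np.array([]), 0.0, True)
    times = peaks / trace.fs_hz
    # amplitude on the unnormalized residual: prominence at the same indices
    # (padded the same way so boundary beats are measurable)
    resid = np.asarray(trace.residual, dtype=float)
    rp = np.concatenate([[resid.min()], resid, [resid.min()]])
    amp = float(np.mean(_peak_prominences(rp, peaks + 1)))
    metrics = BeatMetrics(times, amp, False)
    if peaks.size >= 3:
        ibi_mean, ibi_cv = interbeat_stats(times)
        metrics = BeatMetrics(times, amp, False, ibi_mean, ibi_cv)
    return metrics


def _peak_prominences(x: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    from scipy.signal import peak_prominences

    if peaks.size == 0:
        return np.array([])
    return peak_prominences(x, peaks)[0]


def interbeat_stats(beat_times: np.ndarray) -> tuple[float, float]:
    """Mean and coefficient of variation (sample sd, n-1) of IBIs."""
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size < 3:
        raise InsufficientDataError(
            f"need >= 3 beats for interbeat statistics, got {beat_times.size}"
        )
    ibis = np.diff(beat_times)
    mean = float(ibis.mean())
    cv = float(ibis.std(ddof=1) / mean)
    return mean, cv


def detect_calcium_events(
    trace: IntensityTrace,
    threshold_dff: float = DEFAULT_THRESHOLD_DFF,
    f0_percentile: float = DEFAULT_F0_PERCENTILE,
) -> CalciumEvents:
    """Call Ca2+ transients by thresholding Delta-F/F0.

    F0 is the running ``f0_percentile``-th percentile of the raw trace over a
    centered 60 s window.  One event per contiguous supra-threshold run;
    onset is the first supra-threshold sample, amplitude the run maximum.
    """
    if not 0 < f0_percentile < 50:
        raise InvalidParameterError("f0_percentile must be in (0, 50)")
    if not threshold_dff > 0:
        raise InvalidParameterError("threshold_dff must be > 0")
    f = np.asarray(trace.values, dtype=float)
    win = max(3, int(round(F0_WINDOW_S * trace.fs_hz)) | 1)  # odd
    f0 = percentile_filter(f, f0_percentile, size=win, mode="nearest")
    if np.any(f0 <= 0):
        raise DataError("running F0 estimate is non-positive")
    dff = (f - f0) / f0
    above = dff >= threshold_dff
    edges = np.diff(above.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    onsets = []
    amps = []
    for s, e in zip(starts, ends):
        # one event per excursion; a run is additionally split where a new
        # transient stacks on the decay tail of the previous one — either a
        # one-sample jump >= threshold (instant-rise kernel) or, after
        # falling by >= threshold from the peak, a re-rise >= threshold
        # above the valley
        onset_i, base, peak = s, 0.0, float(dff[s])
        valley = None
        for i in range(s + 1, e):
            x = float(dff[i])
            prev = float(dff[i - 1])
            jump = x - prev >= threshold_dff
            rerise = valley is not None and x - valley >= threshold_dff
            if jump or rerise:
                onsets.append(onset_i / trace.fs_hz)
                amps.append(peak - base)
                onset_i, base, peak = i, (valley if rerise else prev), x
                valley = None
                continue
            if valley is None:
                if x > peak:
                    peak = x
                elif peak - x >= threshold_dff:
                    valley = x
            elif x < valley:
                valley = x
        onsets.append(onset_i / trace.fs_hz)
        amps.append(peak - base)
    return CalciumEvents(
        onset_times=np.asarray(onsets),
        amplitudes_dff=np.asarray(amps),
        f0_estimate=float(np.median(f0)),
        fs_hz=trace.fs_hz,
        dff=dff,
    )


def compound_response(
    events: CalciumEvents, t_add_s: float, window_s: float
) -> dict:
    """Maximum Delta-F/F0 inside ``[t_add, t_add + window_s]``.

    Returns the response alongside the pre-addition spontaneous maximum for
    contrast.  A window running past the recording end triggers a
    :class:`TruncatedWindowWarning` and is evaluated on the available
    samples.
    """
    n = events.dff.size
    duration = n / events.fs_hz
    if not 0 <= t_add_s < duration:
        raise InvalidParameterError(
            f"t_add_s {t_add_s} outside the recording [0, {duration})"
        )
    i0 = int(np.ceil(t_add_s * events.fs_hz - 1e-9))
    i1 = int(np.floor((t_add_s + window_s) * events.fs_hz + 1e-9)) + 1
    if i1 > n:
        warnings.warn(
            f"response window [{t_add_s}, {t_add_s + window_s}] s extends past "
            f"the recording end ({duration} s); truncated",
            TruncatedWindowWarning,
            stacklevel=2,
        )
        i1 = n
    response = float(events.dff[i0:i1].max()) if i1 > i0 else 0.0
    pre = float(events.dff[:i0].max()) if i0 > 0 else 0.0
    return {
        "response_dff": response,
        "pre_addition_max_dff": pre,
        "window_truncated": i1 == n and (t_add_s + window_s) * events.fs_hz > n - 1 + 1e-9,
    }
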