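"""Polynomial trend removal and normalization of intensity traces.

A raw border-ROI trace carries the beat oscillation on top of slow additive
trends (focus drift, evaporation, lamp warm-up).  Preprocessing fits an
ordinary least-squares polynomial in time to the trace, subtracts it, and
optionally z-scores the residual so spectra are comparable across hearts and
dishes.  Amplitude information lives in the *unnormalized* residual, which is
kept alongside (its variance is the band power used by the amplitude
comparisons downstream).

The fit is done in time centered at the trace midpoint for numerical
conditioning; coefficients are stored in that centered basis and converted to
the plain basis for display.

The default degree is 2: enough for slow focus drift without eating
sub-0.2 Hz physiology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.polynomial.polynomial as npoly

from .errors import DataError, UnderdeterminedFitError
from .movie_io import IntensityTrace

__all__ = ["TrendFit", "DetrendedTrace", "fit_trend", "detrend_normalize"]

DEFAULT_DEGREE = 2

#: residual RMS below this fraction of the signal scale marks a flat trace
_FLAT_RTOL = 1e-9


@dataclass(frozen=True)
class TrendFit:
    """Least-squares polynomial trend of a trace.

    ``coeffs_centered`` are ascending-degree coefficients in (t - t_center);
    ``coeffs`` converts them to the plain time basis.
    """

    coeffs_centered: np.ndarray
    t_center: float
    fitted: np.ndarray
    degree: int

    @property
    def coeffs(self) -> np.ndarray:
        """Ascending-degree coefficients in plain (uncentered) time."""
        p = npoly.Polynomial(self.coeffs_centered)
        # compose with (t - t_center)
        shifted = p(npoly.Polynomial([-self.t_center, 1.0]))
        out = np.zeros(self.degree + 1)
        out[: len(shifted.coef)] = shifted.coef
        return out


@dataclass(frozen=True)
class DetrendedTrace:
    """Trace after polynomial trend removal and optional z-scoring.

    ``values`` is the analysis signal (z-scored when ``normalization ==
    "zscore"`` and the residual is not flat); ``residual`` keeps the
    unnormalized detrended samples whose variance (``residual_variance``,
    ddof=0) is the total band power used for amplitude comparisons.
    """

    values: np.ndarray
    residual: np.ndarray
    fs_hz: float
    trend: TrendFit
    normalization: str
    flat: bool
    residual_variance: float
    roi_id: str | None = None

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs_hz

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs_hz

    def as_trace(self) -> IntensityTrace:
        return IntensityTrace(self.values, self.fs_hz, roi_id=self.roi_id)


def fit_trend(trace: IntensityTrace, degree: int = DEFAULT_DEGREE) -> TrendFit:
    """Ordinary least-squares polynomial fit of intensity against time.

    Requires strictly more samples than coefficients (length > degree + 1)
    and all-finite values.
    """
    if degree < 0:
        raise UnderdeterminedFitError(f"degree must be >= 0, got {degree}")
    y = np.asarray(trace.values, dtype=float)
    n = y.size
    if n <= degree + 1:
        raise UnderdeterminedFitError(
            f"trace of length {n} cannot support a degree-{degree} fit"
        )
    if not np.all(np.isfinite(y)):
        raise DataError("trace contains non-finite values")
    t = trace.times
    t_center = float(t[-1]) / 2.0
    tc = t - t_center
    coeffs = npoly.polyfit(tc, y, degree)
    fitted = npoly.polyval(tc, coeffs)
    return TrendFit(np.asarray(coeffs, dtype=float), t_center, fitted, degree)


def detrend_normalize(
    trace: IntensityTrace,
    degree: int = DEFAULT_DEGREE,
    normalization: str = "zscore",
) -> DetrendedTrace:
    """Remove the fitted trend and normalize the residual.

    With ``normalization="zscore"`` the residual is scaled to mean 0, sd 1
    (population sd).  A residual whose RMS is below 1e-9 of the signal scale
    is flagged flat and returned as all zeros instead of dividing by zero.
    """
    if normalization not in ("zscore", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    fit = fit_trend(trace, degree)
    y = np.asarray(trace.values, dtype=float)
    residual = y - fit.fitted
    scale = max(float(np.sqrt(np.mean(y**2))), 1.0)
    rms = float(np.sqrt(np.mean(residual**2)))
    flat = rms <= _FLAT_RTOL * scale
    variance = float(np.var(residual))
    if flat:
        values = np.zeros_like(residual)
    elif normalization == "zscore":
        values = (residual - residual.mean()) / residual.std()
    else:
        values = residual.copy()
    return DetrendedTrace(
        values=values,
        residual=residual,
        fs_hz=trace.fs_hz,
        trend=fit,
        normalization=normalization,
        flat=flat,
        residual_variance=variance,
        roi_id=trace.roi_id,
    )
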