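"""Shared helpers for the test suite.

Everything is generated programmatically; no stored fixtures.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cardiospec.movie_io import IntensityTrace
from cardiospec.synthetic_dish import (
    TRACE_GAIN,
    TRACE_OFFSET,
    ContractionModel,
    contraction_waveform,
    make_beat_schedule,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS_BEAT_HZ = 5.0


def synth_beat_trace(
    model: ContractionModel,
    duration_s: float,
    seed: int,
    noise_sd: float = 0.0,
    drift: tuple[float, ...] | None = None,
    fs_hz: float = FS_BEAT_HZ,
):
    """Noise/drift-augmented border-ROI style pulse trace + its schedule."""
    sched = make_beat_schedule(model, duration_s, seed)
    n = int(round(fs_hz * duration_s))
    t = np.arange(n) / fs_hz
    v = TRACE_OFFSET + TRACE_GAIN * model.amplitude_frac * contraction_waveform(
        t, model, sched.realized_times
    )
    if drift is not None:
        v = v + np.polynomial.polynomial.polyval(t, np.asarray(drift))
    if noise_sd > 0:
        v = v + np.random.default_rng(seed + 990_000).normal(0.0, noise_sd, n)
    return IntensityTrace(v, fs_hz, roi_id="h1"), sched


def match_beats(detected: np.ndarray, truth: np.ndarray, tol_s: float = 0.4):
    """Greedy one-to-one matching; returns (tp, n_detected, n_truth)."""
    used = np.zeros(len(truth), dtype=bool)
    tp = 0
    for bt in detected:
        if len(truth) == 0:
            break
        d = np.abs(truth - bt)
        d = np.where(used, np.inf, d)
        j = int(np.argmin(d))
        if d[j] <= tol_s:
            used[j] = True
            tp += 1
    return tp, len(detected), len(truth)


def brute_force_one_sided_periodogram(x: np.ndarray, fs_hz: float):
    """Independent O(N^2) DFT oracle under the package's power convention."""
    x = np.asarray(x, dtype=float)
    n = x.size
    k = np.arange(n // 2 + 1)
    ang = -2j * np.pi * np.outer(k, np.arange(n)) / n
    X = (np.exp(ang) * x).sum(axis=1)
    p = np.abs(X) ** 2 / n**2
    p[1:] *= 2.0
    if n % 2 == 0:
        p[-1] /= 2.0
    return k * fs_hz / n, p


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
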