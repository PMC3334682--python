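"""Synthetic dishes of beating hearts with known ground truth.

No public dataset of ex vivo heart screening movies exists, so every
downstream stage is tested against this generator.  It emulates:

* brightfield movies of 3-5 hearts embedded in a dish, each an ellipse of
  dark tissue on a bright background whose semi-axes dilate with the
  contraction waveform, sampled at 5 Hz;
* slow additive intensity trends (focus drift, evaporation) as a polynomial
  in time, plus white Gaussian camera noise;
* Ca2+ reporter traces sampled at 0.5 Hz: a baseline with spontaneous
  transients (instant rise, exponential decay) arriving as a Poisson process,
  and an optional compound-evoked transient;
* screening sessions: ordered baseline / compound / wash segments where a
  compound overrides the contraction parameters (frequency shift, amplitude
  suppression, irregularity, arrest) and a wash relaxes them back to baseline
  with an exponential time constant.

Beat timing model: inter-beat intervals are drawn from a gamma distribution
with mean 1/f and a given coefficient of variation (positive support,
tunable irregularity); scheduled beats are independently omitted with
``skip_prob``.  The default contraction waveform is a raised-cosine pulse of
duty cycle 0.3 per beat — brightfield beats are pulse-like, which also
exercises harmonics in the spectrum; a pure sinusoid is offered for analytic
tests.

Everything is seeded: identical config + seed gives bit-identical movies,
traces and ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import GeometryError, InvalidParameterError, ProtocolError
from .movie_io import IntensityTrace, MovieStack, TraceTable

__all__ = [
    "ContractionModel",
    "HeartGeometry",
    "DishConfig",
    "CalciumSimConfig",
    "BeatSchedule",
    "HeartTruth",
    "GroundTruth",
    "CalciumTruth",
    "SegmentSpec",
    "SessionSim",
    "make_beat_schedule",
    "contraction_waveform",
    "render_heart_movie",
    "simulate_calcium_trace",
    "simulate_session",
    "beat_signal_rms",
    "noise_sd_for_snr",
    "recovery_crossing_time",
    "default_dish",
    "TRACE_OFFSET",
    "TRACE_GAIN",
]

#: trace-mode rendering constants: a border-ROI trace is emulated directly as
#: offset + gain * amplitude_frac * s(t); gain 200 a.u. makes the default
#: amplitude_frac of 0.15 a 30 a.u. pulse on a 500 a.u. pedestal.
TRACE_OFFSET = 500.0
TRACE_GAIN = 200.0


# ---------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class ContractionModel:
    """Parameters of one heart's beating.

    ``amplitude_frac`` is the fractional dilation of the heart semi-axes at
    pulse peak; ``ibi_jitter_cv`` the coefficient of variation of inter-beat
    intervals; ``skip_prob`` the probability that a scheduled beat is
    omitted; ``arrest_after_s`` stops all beats beyond that time (measured
    from the start of the schedule).
    """

    beat_freq_hz: float = 1.0
    amplitude_frac: float = 0.15
    waveform: str = "pulse"  # {"pulse", "sinusoid"}
    duty_cycle: float = 0.3
    ibi_jitter_cv: float = 0.05
    skip_prob: float = 0.0
    arrest_after_s: float | None = None

    def __post_init__(self) -> None:
        if not self.beat_freq_hz > 0:
            raise InvalidParameterError(f"beat_freq_hz must be > 0, got {self.beat_freq_hz}")
        if not 0 <= self.amplitude_frac < 1:
            raise InvalidParameterError(
                f"amplitude_frac must be in [0, 1), got {self.amplitude_frac}"
            )
        if self.waveform not in ("pulse", "sinusoid"):
            raise InvalidParameterError(f"unknown waveform {self.waveform!r}")
        if not 0 < self.duty_cycle <= 1:
            raise InvalidParameterError(f"duty_cycle must be in (0, 1], got {self.duty_cycle}")
        if not 0 <= self.skip_prob <= 1:
            raise InvalidParameterError(f"skip_prob must be in [0, 1], got {self.skip_prob}")
        if self.ibi_jitter_cv < 0:
            raise InvalidParameterError(f"ibi_jitter_cv must be >= 0, got {self.ibi_jitter_cv}")
        if self.arrest_after_s is not None and self.arrest_after_s < 0:
            raise InvalidParameterError("arrest_after_s must be >= 0 when set")


@dataclass(frozen=True)
class HeartGeometry:
    """Ellipse placement of one heart: center and semi-axes in pixels."""

    center: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]  # (a_row, a_col), pixels
    interior: float = 400.0  # dark tissue on a bright field


@dataclass(frozen=True)
class DishConfig:
    """A dish: hearts, background, drift, noise, acquisition parameters."""

    hearts: tuple[HeartGeometry, ...]
    contractions: tuple[ContractionModel, ...]
    seed: int
    background: float = 1000.0
    drift_coeffs: tuple[float, ...] = (0.0,)  # ascending powers of t (a.u./s^k)
    noise_sd: float = 2.0
    fs_hz: float = 5.0
    duration_s: float = 120.0
    frame_shape: tuple[int, int] = (96, 96)

    def __post_init__(self) -> None:
        if not self.fs_hz > 0:
            raise InvalidParameterError(f"fs_hz must be > 0, got {self.fs_hz}")
        if not self.duration_s > 0:
            raise InvalidParameterError(f"duration_s must be > 0, got {self.duration_s}")
        if len(self.hearts) < 1:
            raise InvalidParameterError("need >= 1 heart")
        if len(self.hearts) != len(self.contractions):
            raise InvalidParameterError("hearts and contractions must pair up")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.fs_hz * self.duration_s))

    def validate_geometry(self) -> None:
        nrow, ncol = self.frame_shape
        for i, (h, m) in enumerate(zip(self.hearts, self.contractions)):
            dil = 1.0 + m.amplitude_frac
            r0, c0 = h.center
            a, b = h.semi_axes
            if (
                r0 - a * dil < 0
                or r0 + a * dil > nrow - 1
                or c0 - b * dil < 0
                or c0 + b * dil > ncol - 1
            ):
                raise GeometryError(
                    f"heart {i} exceeds frame bounds at maximal dilation "
                    f"(center {h.center}, semi-axes {h.semi_axes}, x{dil:.3f})"
                )


@dataclass(frozen=True)
class CalciumSimConfig:
    """Ca2+ trace simulation: spontaneous Poisson transients + compound step."""

    seed: int
    fs_hz: float = 0.5
    duration_s: float = 1200.0
    baseline_f0: float = 1000.0
    spontaneous_rate_hz: float = 0.02
    event_amplitude_dff: float = 0.5  # transient peak as a Delta-F/F0 fraction
    event_decay_s: float = 20.0
    compound_add_time_s: float | None = None
    compound_response_dff: float = 1.2
    compound_decay_s: float = 60.0
    noise_sd: float = 0.0  # intensity units
    forced_events: tuple[tuple[float, float], ...] = ()  # (time_s, amplitude_dff)

    def __post_init__(self) -> None:
        if not self.fs_hz > 0:
            raise InvalidParameterError(f"fs_hz must be > 0, got {self.fs_hz}")
        if not self.duration_s > 0:
            raise InvalidParameterError("duration_s must be > 0")
        if self.spontaneous_rate_hz < 0:
            raise InvalidParameterError("spontaneous_rate_hz must be >= 0")
        if not self.baseline_f0 > 0:
            raise InvalidParameterError("baseline_f0 must be > 0")
        if not self.event_decay_s > 0 or not self.compound_decay_s > 0:
            raise InvalidParameterError("decay constants must be > 0")


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class BeatSchedule:
    """Scheduled and realized beat times of one heart."""

    scheduled_times: np.ndarray
    realized_times: np.ndarray

    def __post_init__(self) -> None:
        self.scheduled_times = np.asarray(self.scheduled_times, dtype=float)
        self.realized_times = np.asarray(self.realized_times, dtype=float)


@dataclass
class HeartTruth:
    heart_id: str
    scheduled_times: np.ndarray
    realized_times: np.ndarray
    amplitudes: np.ndarray  # amplitude_frac in force at each realized beat
    model: ContractionModel

    @property
    def instantaneous_freq_hz(self) -> np.ndarray:
        """1 / inter-beat interval at each realized beat after the first."""
        return 1.0 / np.diff(self.realized_times)

    def to_dict(self) -> dict:
        return {
            "heart_id": self.heart_id,
            "scheduled_times": self.scheduled_times.tolist(),
            "realized_times": self.realized_times.tolist(),
            "amplitudes": self.amplitudes.tolist(),
            "beat_freq_hz": self.model.beat_freq_hz,
            "amplitude_frac": self.model.amplitude_frac,
            "ibi_jitter_cv": self.model.ibi_jitter_cv,
            "skip_prob": self.model.skip_prob,
        }


@dataclass
class GroundTruth:
    hearts: list[HeartTruth]
    drift_coeffs: tuple[float, ...]
    seed: int

    def to_dict(self) -> dict:
        return {
            "hearts": [h.to_dict() for h in self.hearts],
            "drift_coeffs": list(self.drift_coeffs),
            "seed": self.seed,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


@dataclass
class CalciumTruth:
    """True Ca2+ event onsets (snapped to the sample grid) and amplitudes."""

    event_times: np.ndarray
    event_amplitudes_dff: np.ndarray
    compound_time_s: float | None
    compound_amplitude_dff: float | None
    seed: int

    def to_dict(self) -> dict:
        return {
            "event_times": self.event_times.tolist(),
            "event_amplitudes_dff": self.event_amplitudes_dff.tolist(),
            "compound_time_s": self.compound_time_s,
            "compound_amplitude_dff": self.compound_amplitude_dff,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# beat scheduling


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def make_beat_schedule(
    model: ContractionModel, duration_s: float, seed=0
) -> BeatSchedule:
    """Draw scheduled and realized beat times over ``[0, duration_s]``.

    The first beat falls at half a mean period; subsequent gaps are exactly
    ``1/beat_freq_hz`` when ``ibi_jitter_cv == 0``, else gamma-distributed
    with that mean and CV.  Each scheduled beat is independently omitted with
    ``skip_prob``; with ``arrest_after_s`` set, no beat occurs beyond it.
    """
    if not duration_s > 0:
        raise InvalidParameterError(f"duration_s must be > 0, got {duration_s}")
    rng = _as_rng(seed)
    f = model.beat_freq_hz
    cv = model.ibi_jitter_cv
    mean_ibi = 1.0 / f
    limit = duration_s if model.arrest_after_s is None else min(
        duration_s, model.arrest_after_s
    )
    times = []
    t = 0.5 * mean_ibi
    while t <= limit + 1e-12:
        times.append(t)
        if cv == 0:
            gap = mean_ibi
        else:
            shape = 1.0 / cv**2
            gap = rng.gamma(shape, mean_ibi / shape)
        t += gap
    scheduled = np.asarray(times)
    if model.skip_prob > 0 and scheduled.size:
        keep = rng.random(scheduled.size) >= model.skip_prob
        realized = scheduled[keep]
    else:
        realized = scheduled.copy()
    return BeatSchedule(scheduled, realized)


def contraction_waveform(
    t: np.ndarray,
    model: ContractionModel,
    beat_times: np.ndarray,
    amplitudes: np.ndarray | None = None,
) -> np.ndarray:
    """Contraction signal s(t) sampled at ``t``.

    ``pulse``: a raised-cosine bump of width ``duty_cycle / beat_freq_hz``
    centered on each beat time, peak 1 (times optional per-beat amplitude
    scale).  ``sinusoid``: ``sin(2 pi f t)``, ignoring the beat schedule —
    it exists for analytic tests.
    """
    t = np.asarray(t, dtype=float)
    if model.waveform == "sinusoid":
        return np.sin(2 * np.pi * model.beat_freq_hz * t)
    s = np.zeros_like(t)
    if len(beat_times) == 0:
        return s
    width = model.duty_cycle / model.beat_freq_hz
    if amplitudes is None:
        amplitudes = np.ones(len(beat_times))
    dt = t[1] - t[0] if t.size > 1 else 1.0
    for tb, amp in zip(beat_times, amplitudes):
        i0 = max(0, int(np.ceil((tb - width / 2 - t[0]) / dt)))
        i1 = min(t.size, int(np.floor((tb + width / 2 - t[0]) / dt)) + 1)
        if i0 >= i1:
            continue
        phase = (t[i0:i1] - (tb - width / 2)) / width
        s[i0:i1] += amp * 0.5 * (1.0 - np.cos(2 * np.pi * phase))
    return s


# ---------------------------------------------------------------------------
# movie rendering


def _render_frames(
    config: DishConfig,
    waveforms: list[np.ndarray],
    noise_rng: np.random.Generator,
) -> np.ndarray:
    n = config.n_frames
    nrow, ncol = config.frame_shape
    t = np.arange(n) / config.fs_hz
    frames = np.full((n, nrow, ncol), float(config.background))
    rr, cc = np.mgrid[0:nrow, 0:ncol]
    for h, m, s in zip(config.hearts, config.contractions, waveforms):
        r0, c0 = h.center
        a, b = h.semi_axes
        dr2 = (rr - r0) ** 2
        dc2 = (cc - c0) ** 2
        scale = 1.0 + m.amplitude_frac * s
        # pixel-center membership of the dilated ellipse, per frame
        prev_k = None
        mask = None
        for i in range(n):
            k = scale[i]
            if prev_k is None or k != prev_k:
                mask = dr2 / (a * k) ** 2 + dc2 / (b * k) ** 2 <= 1.0
                prev_k = k
            frames[i][mask] = h.interior
    if any(c != 0.0 for c in config.drift_coeffs):
        drift = np.polynomial.polynomial.polyval(t, np.asarray(config.drift_coeffs))
        frames += drift[:, None, None]
    if config.noise_sd > 0:
        frames += noise_rng.normal(0.0, config.noise_sd, frames.shape)
    return frames


def render_heart_movie(config: DishConfig) -> tuple[MovieStack, GroundTruth]:
    """Render the dish as a grayscale movie with its ground-truth sidecar."""
    config.validate_geometry()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.hearts) + 1)
    t = np.arange(config.n_frames) / config.fs_hz
    waveforms = []
    hearts_truth = []
    for i, m in enumerate(config.contractions):
        rng = np.random.default_rng(children[i])
        sched = make_beat_schedule(m, config.duration_s, rng)
        waveforms.append(contraction_waveform(t, m, sched.realized_times))
        hearts_truth.append(
            HeartTruth(
                heart_id=f"heart{i + 1}",
                scheduled_times=sched.scheduled_times,
                realized_times=sched.realized_times,
                amplitudes=np.full(sched.realized_times.size, m.amplitude_frac),
                model=m,
            )
        )
    noise_rng = np.random.default_rng(children[-1])
    frames = _render_frames(config, waveforms, noise_rng)
    stack = MovieStack(frames, config.fs_hz, source="synthetic")
    truth = GroundTruth(hearts_truth, config.drift_coeffs, config.seed)
    return stack, truth


def default_dish(
    n_hearts: int = 4,
    seed: int = 0,
    contraction: ContractionModel | None = None,
    **kwargs,
) -> DishConfig:
    """A standard dish layout: ``n_hearts`` ellipses on a regular grid."""
    if not 1 <= n_hearts <= 9:
        raise InvalidParameterError("default layout supports 1-9 hearts")
    frame_shape = kwargs.pop("frame_shape", (96, 96))
    nrow, ncol = frame_shape
    per_side = int(math.ceil(math.sqrt(n_hearts)))
    hearts = []
    for i in range(n_hearts):
        gr, gc = divmod(i, per_side)
        r0 = (gr + 0.5) * nrow / per_side
        c0 = (gc + 0.5) * ncol / per_side
        ax = 0.22 * nrow / per_side
        hearts.append(HeartGeometry(center=(r0, c0), semi_axes=(ax, 0.8 * ax)))
    model = contraction or ContractionModel()
    return DishConfig(
        hearts=tuple(hearts),
        contractions=tuple([model] * n_hearts),
        seed=seed,
        frame_shape=frame_shape,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# calcium traces


def simulate_calcium_trace(
    config: CalciumSimConfig,
) -> tuple[IntensityTrace, CalciumTruth]:
    """Baseline + spontaneous transients + optional compound response + noise.

    Transients rise instantly and decay exponentially; onsets are snapped to
    the sample grid (first sample at or after the drawn arrival time), so a
    noise-free transient of amplitude A peaks at exactly ``baseline_f0 * (1 +
    A)`` on its onset sample.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.fs_hz * config.duration_s))
    t = np.arange(n) / config.fs_hz
    f0 = config.baseline_f0
    trace = np.full(n, f0)

    event_times = []
    event_amps = []
    if config.spontaneous_rate_hz > 0:
        te = rng.exponential(1.0 / config.spontaneous_rate_hz)
        while te < config.duration_s:
            event_times.append(te)
            event_amps.append(config.event_amplitude_dff)
            te += rng.exponential(1.0 / config.spontaneous_rate_hz)
    for te, amp in config.forced_events:
        event_times.append(float(te))
        event_amps.append(float(amp))
    order = np.argsort(event_times, kind="stable")
    snapped = []
    snapped_amps = []
    for j in order:
        te, amp = event_times[j], event_amps[j]
        i_on = int(np.ceil(te * config.fs_hz - 1e-9))
        if i_on >= n:
            continue
        t_on = t[i_on]
        trace[i_on:] += f0 * amp * np.exp(-(t[i_on:] - t_on) / config.event_decay_s)
        snapped.append(t_on)
        snapped_amps.append(amp)

    comp_time = None
    if config.compound_add_time_s is not None:
        i_on = int(np.ceil(config.compound_add_time_s * config.fs_hz - 1e-9))
        if i_on < n:
            comp_time = t[i_on]
            trace[i_on:] += (
                f0
                * config.compound_response_dff
                * np.exp(-(t[i_on:] - comp_time) / config.compound_decay_s)
            )
    if config.noise_sd > 0:
        trace = trace + rng.normal(0.0, config.noise_sd, n)
    truth = CalciumTruth(
        event_times=np.asarray(snapped),
        event_amplitudes_dff=np.asarray(snapped_amps),
        compound_time_s=comp_time,
        compound_amplitude_dff=(
            config.compound_response_dff if comp_time is not None else None
        ),
        seed=config.seed,
    )
    return IntensityTrace(trace, config.fs_hz, roi_id="ca"), truth


# ---------------------------------------------------------------------------
# screening sessions


@dataclass(frozen=True)
class SegmentSpec:
    """One protocol segment.

    ``override`` replaces the baseline contraction parameters during a
    compound segment (and, if given on a wash segment, during the wash —
    e.g. an arrest that never resumes).  ``wash_tau_s`` relaxes the
    preceding compound's parameters back to baseline exponentially; a wash
    without it returns to baseline instantly.
    """

    label: str
    duration_s: float
    override: ContractionModel | None = None
    wash_tau_s: float | None = None
    compound_name: str | None = None
    concentration_um: float | None = None

    def __post_init__(self) -> None:
        if self.label not in ("baseline", "compound", "wash"):
            raise ProtocolError(f"unknown segment label {self.label!r}")
        if not self.duration_s > 0:
            raise ProtocolError("segment duration must be > 0")


@dataclass
class SessionTruth:
    """Ground truth of a simulated session, incl. closed-form wash recovery."""

    hearts: list[HeartTruth]
    segments: list[tuple[str, float, float]]  # (label, start_s, end_s)
    baseline_model: ContractionModel
    segment_models: list[ContractionModel]  # model in force per segment
    wash_relaxations: list[dict]  # {"start_s", "f_from", "f_to", "tau_s"} per wash
    seed: int


@dataclass
class SessionSim:
    table: TraceTable | None
    movie: MovieStack | None
    events: list[dict]
    truth: SessionTruth
    fs_hz: float


def _segment_params(
    protocol: Sequence[SegmentSpec], base: ContractionModel
) -> tuple[list[ContractionModel], list[dict]]:
    """Model in force per segment plus wash relaxation descriptors."""
    models: list[ContractionModel] = []
    washes: list[dict] = []
    t0 = 0.0
    prev_model = base
    for seg in protocol:
        if seg.label == "baseline":
            m = base
        elif seg.label == "compound":
            m = seg.override if seg.override is not None else base
        else:  # wash
            if seg.override is not None:
                m = seg.override
            else:
                m = base  # relaxation handled continuously via wash_tau_s
            washes.append(
                {
                    "start_s": t0,
                    "f_from": prev_model.beat_freq_hz,
                    "f_to": base.beat_freq_hz,
                    "amp_from": prev_model.amplitude_frac,
                    "amp_to": base.amplitude_frac,
                    "tau_s": seg.wash_tau_s,
                }
            )
        models.append(m)
        prev_model = m
        t0 += seg.duration_s
    return models, washes


def _param_at(
    t: float,
    protocol: Sequence[SegmentSpec],
    seg_bounds: list[tuple[float, float]],
    models: list[ContractionModel],
    base: ContractionModel,
) -> tuple[float, float, float, float, bool]:
    """(freq, amplitude_frac, jitter_cv, skip_prob, arrested) at time t."""
    for i, (start, end) in enumerate(seg_bounds):
        if start <= t < end or (i == len(seg_bounds) - 1 and t >= start):
            seg = protocol[i]
            m = models[i]
            arrested = (
                m.arrest_after_s is not None and t - start >= m.arrest_after_s
            )
            if seg.label == "wash" and seg.override is None and seg.wash_tau_s:
                prev_m = models[i - 1] if i > 0 else base
                decay = math.exp(-(t - start) / seg.wash_tau_s)
                f = base.beat_freq_hz + (prev_m.beat_freq_hz - base.beat_freq_hz) * decay
                amp = base.amplitude_frac + (
                    prev_m.amplitude_frac - base.amplitude_frac
                ) * decay
                cv = base.ibi_jitter_cv + (prev_m.ibi_jitter_cv - base.ibi_jitter_cv) * decay
                skip = base.skip_prob + (prev_m.skip_prob - base.skip_prob) * decay
                # relaxation always resumes beating; a persistent arrest is
                # expressed with an explicit wash override instead
                return f, amp, cv, skip, False
            return m.beat_freq_hz, m.amplitude_frac, m.ibi_jitter_cv, m.skip_prob, arrested
    raise ValueError(f"time {t} outside session")  # pragma: no cover


def simulate_session(
    dish: DishConfig,
    protocol: Sequence[SegmentSpec],
    render: str = "trace",
    trace_noise_sd: float | None = None,
) -> SessionSim:
    """Simulate a full screening session.

    ``render="trace"`` emulates the border-ROI trace of each heart directly
    (offset + gain * amplitude_frac * s(t) + drift + noise) — fast, used for
    statistical calibration; ``render="movie"`` renders the concatenated
    frames through the full optical model.

    The first segment must be ``baseline``.  The returned event log holds one
    ``add_compound`` / ``start_wash`` entry per segment boundary.
    """
    if len(protocol) == 0 or protocol[0].label != "baseline":
        raise ProtocolError("protocol must start with a baseline segment")
    if render not in ("trace", "movie"):
        raise InvalidParameterError(f"unknown render mode {render!r}")
    for prev, cur in zip(protocol, protocol[1:]):
        if cur.label == "compound" and prev.label == "compound":
            raise ProtocolError("compound segments must be separated by a wash or baseline")

    total_s = sum(seg.duration_s for seg in protocol)
    seg_bounds = []
    t0 = 0.0
    for seg in protocol:
        seg_bounds.append((t0, t0 + seg.duration_s))
        t0 += seg.duration_s
    n = int(round(dish.fs_hz * total_s))
    t = np.arange(n) / dish.fs_hz

    ss = np.random.SeedSequence(dish.seed)
    children = ss.spawn(len(dish.hearts) + 1)

    hearts_truth = []
    waveforms = []
    for i, base in enumerate(dish.contractions):
        rng = np.random.default_rng(children[i])
        models, washes = _segment_params(protocol, base)
        # sequential walk through the session with locally-valid parameters
        sched_times: list[float] = []
        real_times: list[float] = []
        real_amps: list[float] = []
        f0, _, _, _, _ = _param_at(0.0, protocol, seg_bounds, models, base)
        tb = 0.5 / f0
        while tb < total_s:
            f, amp, cv, skip, arrested = _param_at(tb, protocol, seg_bounds, models, base)
            sched_times.append(tb)
            omitted = arrested or (skip > 0 and rng.random() < skip)
            if not omitted:
                real_times.append(tb)
                real_amps.append(amp)
            mean_ibi = 1.0 / f
            if cv == 0:
                gap = mean_ibi
            else:
                shape = 1.0 / cv**2
                gap = rng.gamma(shape, mean_ibi / shape)
            tb += gap
        real_times_arr = np.asarray(real_times)
        real_amps_arr = np.asarray(real_amps)
        # per-beat amplitude enters as a scale relative to the baseline peak
        rel = real_amps_arr / max(base.amplitude_frac, 1e-12)
        waveforms.append(contraction_waveform(t, base, real_times_arr, rel))
        hearts_truth.append(
            HeartTruth(
                heart_id=f"heart{i + 1}",
                scheduled_times=np.asarray(sched_times),
                realized_times=real_times_arr,
                amplitudes=real_amps_arr,
                model=base,
            )
        )

    noise_rng = np.random.default_rng(children[-1])
    events = []
    for (start, _), seg in zip(seg_bounds, protocol):
        if seg.label == "compound":
            events.append(
                {
                    "time_s": start,
                    "action": "add_compound",
                    "compound": {
                        "name": seg.compound_name or "compound",
                        "concentration_um": (
                            10.0 if seg.concentration_um is None else seg.concentration_um
                        ),
                        "solvent": "DMSO",
                    },
                }
            )
        elif seg.label == "wash":
            events.append({"time_s": start, "action": "start_wash"})

    base0 = dish.contractions[0]
    models0, washes0 = _segment_params(protocol, base0)
    truth = SessionTruth(
        hearts=hearts_truth,
        segments=[(seg.label, s, e) for seg, (s, e) in zip(protocol, seg_bounds)],
        baseline_model=base0,
        segment_models=models0,
        wash_relaxations=washes0,
        seed=dish.seed,
    )

    if render == "movie":
        long_dish = replace(dish, duration_s=total_s)
        long_dish.validate_geometry()
        frames = _render_frames(long_dish, waveforms, noise_rng)
        movie = MovieStack(frames, dish.fs_hz, source="synthetic")
        return SessionSim(table=None, movie=movie, events=events, truth=truth, fs_hz=dish.fs_hz)

    sd = dish.noise_sd if trace_noise_sd is None else trace_noise_sd
    traces = {}
    for i, (base, wave) in enumerate(zip(dish.contractions, waveforms)):
        vals = TRACE_OFFSET + TRACE_GAIN * base.amplitude_frac * wave
        if any(c != 0.0 for c in dish.drift_coeffs):
            vals = vals + np.polynomial.polynomial.polyval(
                t, np.asarray(dish.drift_coeffs)
            )
        if sd > 0:
            vals = vals + noise_rng.normal(0.0, sd, n)
        traces[f"heart{i + 1}"] = vals
    table = TraceTable.from_traces(t, traces, fs_hz=dish.fs_hz)
    return SessionSim(table=table, movie=None, events=events, truth=truth, fs_hz=dish.fs_hz)


# ---------------------------------------------------------------------------
# analytic helpers


def beat_signal_rms(model: ContractionModel, gain: float = TRACE_GAIN) -> float:
    """RMS (about the mean) of the noise-free trace-mode beat component.

    For a raised-cosine pulse train of height h = gain * amplitude_frac and
    duty d: E[s] = d/2, E[s^2] = 3d/8, so var = h^2 (3d/8 - d^2/4).
    """
    h = gain * model.amplitude_frac
    d = model.duty_cycle
    return h * math.sqrt(3 * d / 8 - (d / 2) ** 2)


def noise_sd_for_snr(
    model: ContractionModel, snr: float, gain: float = TRACE_GAIN
) -> float:
    """Trace noise sd giving the requested RMS signal-to-noise ratio."""
    if not snr > 0:
        raise InvalidParameterError("snr must be > 0")
    return beat_signal_rms(model, gain) / snr


def recovery_crossing_time(
    f_baseline_hz: float, f_compound_hz: float, tau_s: float, tol_hz: float
) -> float:
    """Closed-form time (from wash start) at which the exponentially relaxing
    beat frequency re-enters ``tol_hz`` of baseline."""
    delta = abs(f_compound_hz - f_baseline_hz)
    if delta <= tol_hz:
        return 0.0
    return tau_s * math.log(delta / tol_hz)
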