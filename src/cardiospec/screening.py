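"""The screening loop: segment sessions, evaluate compounds, detect washout
recovery, and emit per-dish reports.

A session is an ordered sequence of contiguous segments labelled
``baseline`` / ``compound`` / ``wash``; the first must be a baseline (the
control reading).  Each heart is analyzed independently — per-heart traces
are detrended, transformed to power spectra and compared
baseline-vs-compound; the wash segment is scanned with a sliding window
until it again "resembles the initial control reading", operationalized as
two consecutive windows classified ``no_effect`` (the hysteresis prevents
flicker).  Defaults of 30 s windows stepped by 10 s give >= 15 beats per
window even at 0.5 Hz beating.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .beat_calcium import BeatMetrics, detect_beats
from .errors import (
    CardiospecError,
    InsufficientDataError,
    InvalidParameterError,
    ProtocolError,
)
from .movie_io import (
    IntensityTrace,
    TraceTable,
    read_movie,
    read_rois,
    read_trace_table,
    write_json_report,
)
from .preprocess import DEFAULT_DEGREE, DetrendedTrace, detrend_normalize
from .roi_trace import extract_traces
from .spectral import (
    DEFAULT_F_MIN_HZ,
    PowerSpectrum,
    SpectralComparison,
    compare_spectra,
    power_spectrum,
)

__all__ = [
    "CompoundRecord",
    "SessionEvent",
    "Segment",
    "ScreenSession",
    "RecoveryResult",
    "CompoundEffectReport",
    "segment_session",
    "detect_recovery",
    "evaluate_compound",
    "run_screen",
]

REPORT_SCHEMA_VERSION = 1
DEFAULT_WINDOW_S = 30.0
DEFAULT_STEP_S = 10.0
MIN_BASELINE_S = 30.0
#: seconds discarded at the start of compound and wash segments: a compound
#: pipetted into the dish needs a moment to mix, and the hard slice at the
#: event time would otherwise catch the transition (including a beat pulse
#: straddling the boundary)
DEFAULT_TRANSITION_GUARD_S = 2.0


@dataclass(frozen=True)
class CompoundRecord:
    """Identity of a screened compound; carried verbatim into reports."""

    name: str
    concentration_um: float
    solvent: str = "DMSO"

    def __post_init__(self) -> None:
        if not self.concentration_um > 0:
            raise InvalidParameterError(
                f"concentration_um must be > 0, got {self.concentration_um}"
            )

    @property
    def is_vehicle_control(self) -> bool:
        """True when the 'compound' is the solvent itself (e.g. DMSO)."""
        return self.name.strip().lower() == self.solvent.strip().lower()

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "concentration_um": self.concentration_um,
            "solvent": self.solvent,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CompoundRecord":
        return cls(
            name=d["name"],
            concentration_um=float(d["concentration_um"]),
            solvent=d.get("solvent", "DMSO"),
        )


@dataclass(frozen=True)
class SessionEvent:
    """One entry of the event log: a compound addition or a wash start."""

    time_s: float
    action: str  # {"add_compound", "start_wash"}
    compound: CompoundRecord | None = None

    def __post_init__(self) -> None:
        if self.action not in ("add_compound", "start_wash"):
            raise ProtocolError(f"unknown action {self.action!r}")
        if self.action == "add_compound" and self.compound is None:
            raise ProtocolError("add_compound event needs a compound record")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SessionEvent":
        comp = d.get("compound")
        if isinstance(comp, Mapping):
            comp = CompoundRecord.from_dict(comp)
        return cls(time_s=float(d["time_s"]), action=d["action"], compound=comp)


@dataclass(frozen=True)
class Segment:
    label: str
    start_s: float
    end_s: float
    compound: CompoundRecord | None = None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class ScreenSession:
    """Trace table sliced into ordered baseline/compound/wash segments."""

    table: TraceTable
    segments: list[Segment]

    @property
    def roi_ids(self) -> list[str]:
        return self.table.roi_ids

    def segment_trace(self, segment: Segment, roi_id: str) -> IntensityTrace:
        sub = self.table.slice_time(segment.start_s, segment.end_s)
        return sub.trace(roi_id)


@dataclass(frozen=True)
class RecoveryResult:
    recovery_time_s: float | None  # from wash start; None = not recovered
    window_labels: tuple[str, ...]
    window_starts_s: tuple[float, ...]

    @property
    def recovered(self) -> bool:
        return self.recovery_time_s is not None


@dataclass
class CompoundEffectReport:
    """Per-heart, per-compound verdict with its supporting statistics."""

    roi_id: str
    compound: CompoundRecord | None
    is_control: bool
    comparison: SpectralComparison
    baseline_beats: BeatMetrics
    compound_beats: BeatMetrics
    wash_beats: BeatMetrics | None
    recovery: RecoveryResult | None
    baseline_spectrum: PowerSpectrum
    compound_spectrum: PowerSpectrum
    metadata: dict = field(default_factory=dict)

    @property
    def classification(self) -> str:
        return self.comparison.classification

    def to_dict(self) -> dict:
        def beats_dict(b: BeatMetrics | None):
            if b is None:
                return None
            return {
                "beat_count": b.beat_count,
                "beat_times_s": b.beat_times.tolist(),
                "mean_rate_bpm": b.mean_rate_bpm,
                "ibi_mean_s": b.ibi_mean_s,
                "ibi_cv": b.ibi_cv,
                "mean_beat_amplitude": b.mean_beat_amplitude,
                "arrest_flag": b.arrest_flag,
            }

        def spec_dict(s: PowerSpectrum):
            return {
                "frequencies_hz": s.frequencies.tolist(),
                "power": s.power.tolist(),
                "fs_hz": s.fs_hz,
                "n_samples": s.n_samples,
                "window": s.window,
                "total_band_power": s.total_band_power,
            }

        c = self.comparison
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "roi_id": self.roi_id,
            "compound": self.compound.to_dict() if self.compound else None,
            "is_control": self.is_control,
            "classification": c.classification,
            "comparison": {
                "jsd": c.jsd,
                "delta_f_dom_hz": c.delta_f_dom,
                "f_dom_baseline_hz": c.f_dom_baseline,
                "f_dom_treated_hz": c.f_dom_treated,
                "band_power_ratio": c.band_power_ratio,
                "null_jsd_q95": c.null_jsd_q95,
                "bin_hz": c.bin_hz,
                "treated_no_peak": c.treated_no_peak,
            },
            "beats": {
                "baseline": beats_dict(self.baseline_beats),
                "compound": beats_dict(self.compound_beats),
                "wash": beats_dict(self.wash_beats),
            },
            "recovery": (
                None
                if self.recovery is None
                else {
                    "recovered": self.recovery.recovered,
                    "recovery_time_s": self.recovery.recovery_time_s,
                    "window_labels": list(self.recovery.window_labels),
                    "window_starts_s": list(self.recovery.window_starts_s),
                }
            ),
            "spectra": {
                "baseline": spec_dict(self.baseline_spectrum),
                "compound": spec_dict(self.compound_spectrum),
            },
            "metadata": self.metadata,
        }


# ---------------------------------------------------------------------------
# operations


def segment_session(
    table: TraceTable, events: Sequence[SessionEvent | Mapping]
) -> ScreenSession:
    """Slice a recording at event times and label the segments.

    The recording before the first event is the baseline control reading; an
    ``add_compound`` opens a compound segment, a ``start_wash`` a wash.
    Violations of the flowchart ordering raise :class:`ProtocolError`.
    """
    evts = [
        e if isinstance(e, SessionEvent) else SessionEvent.from_dict(e) for e in events
    ]
    duration = table.n_samples / table.fs_hz
    if not evts:
        return ScreenSession(table, [Segment("baseline", 0.0, duration)])
    times = [e.time_s for e in evts]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ProtocolError("event times overlap or are out of order")
    if times[0] <= 0.0:
        raise ProtocolError(
            "first event precedes any baseline samples: a control reading is "
            "required before the first compound"
        )
    if times[-1] >= duration:
        raise ProtocolError(f"event at {times[-1]} s is outside the {duration} s recording")
    segments: list[Segment] = [Segment("baseline", 0.0, times[0])]
    current = "baseline"
    for i, e in enumerate(evts):
        end = times[i + 1] if i + 1 < len(evts) else duration
        if e.action == "add_compound":
            if current not in ("baseline", "wash"):
                raise ProtocolError(
                    "add_compound must follow a baseline or wash segment, "
                    f"not {current!r}"
                )
            segments.append(Segment("compound", e.time_s, end, compound=e.compound))
            current = "compound"
        else:
            if current != "compound":
                raise ProtocolError("start_wash must follow a compound segment")
            segments.append(Segment("wash", e.time_s, end))
            current = "wash"
    return ScreenSession(table, segments)


def _windowed_baseline_reference(
    baseline: DetrendedTrace,
    nw: int,
    degree: int,
    spectrum_window: str,
    n_resamples: int,
    seed: int,
) -> tuple[PowerSpectrum, float]:
    """Mean spectrum of baseline windows plus a matched null JSD threshold.

    Wash windows are short, so their spectra carry window-length leakage and
    estimator noise that a full-length baseline spectrum does not.  Comparing
    them against the *average spectrum of equal-length baseline windows*
    (and thresholding with the 95th percentile of JSD between individual
    circularly-shifted baseline windows and that average) keeps the reference
    statistically matched to what is being tested.
    """
    from .spectral import JSD_MIN_EFFECT, _jsd_bits, _rebin

    values = np.asarray(
        baseline.residual, dtype=float
    )  # re-detrended per window below
    fs = baseline.fs_hz
    n = values.size
    step = nw  # non-overlapping windows for the mean reference
    powers = []
    variances = []
    i0 = 0
    while i0 + nw <= n:
        dt = detrend_normalize(IntensityTrace(values[i0 : i0 + nw], fs), degree)
        spec = power_spectrum(dt, spectrum_window)
        powers.append(spec.power)
        variances.append(dt.residual_variance)
        i0 += step
    mean_power = np.mean(powers, axis=0)
    freqs = np.arange(mean_power.size) * (fs / nw)
    ref = PowerSpectrum(
        frequencies=freqs,
        power=mean_power,
        fs_hz=fs,
        n_samples=nw,
        window=spectrum_window,
        total_band_power=float(np.mean(variances)),
        analyzed_mean_square=float(mean_power.sum()),
    )
    # matched null: random circular windows of the baseline vs the reference
    from .spectral import CLASSIFY_BIN_HZ

    bin_hz = max(ref.df_hz, CLASSIFY_BIN_HZ)
    _, ref_coarse = _rebin(freqs, mean_power, bin_hz)
    rng = np.random.default_rng(seed)
    jsds = np.empty(n_resamples)
    for i in range(n_resamples):
        s = int(rng.integers(0, n))
        win = np.take(values, np.arange(s, s + nw), mode="wrap")
        dt = detrend_normalize(IntensityTrace(win, fs), degree)
        spec = power_spectrum(dt, spectrum_window)
        _, coarse = _rebin(spec.frequencies, spec.power, bin_hz)
        m = min(coarse.size, ref_coarse.size)
        jsds[i] = _jsd_bits(ref_coarse[1:m], coarse[1:m])
    q95 = float(np.quantile(jsds, 0.95))
    return ref, max(q95, JSD_MIN_EFFECT)


def detect_recovery(
    baseline: DetrendedTrace,
    wash_trace: IntensityTrace,
    window_s: float = DEFAULT_WINDOW_S,
    step_s: float = DEFAULT_STEP_S,
    degree: int = DEFAULT_DEGREE,
    f_min: float = DEFAULT_F_MIN_HZ,
    spectrum_window: str = "rect",
    seed: int = 0,
) -> RecoveryResult:
    """Scan the wash with a sliding window until the signal resembles baseline.

    Each window is detrended, transformed, and compared against a windowed
    baseline reference of matched length; recovery is declared at the start
    of the first of two consecutive windows classified ``no_effect`` (the
    hysteresis prevents flicker).  Returns ``recovery_time_s`` relative to
    the wash start, or None when the segment ends unrecovered.
    """
    fs = wash_trace.fs_hz
    nw = int(round(window_s * fs))
    step = max(1, int(round(step_s * fs)))
    n = len(wash_trace)
    if n < 2 * nw:
        raise InsufficientDataError(
            f"wash of {n / fs:.1f} s is shorter than two {window_s:.0f} s windows"
        )
    if len(baseline) < nw:
        raise InsufficientDataError("baseline is shorter than one analysis window")
    ref_spec, jsd_thresh = _windowed_baseline_reference(
        baseline, nw, degree, spectrum_window, 200, seed
    )
    labels: list[str] = []
    starts: list[float] = []
    recovery: float | None = None
    values = np.asarray(wash_trace.values, dtype=float)
    i0 = 0
    while i0 + nw <= n:
        seg = IntensityTrace(values[i0 : i0 + nw], fs)
        dt = detrend_normalize(seg, degree)
        spec = power_spectrum(dt, spectrum_window)
        cmp = compare_spectra(
            ref_spec, spec, baseline, f_min=f_min, jsd_threshold=jsd_thresh, seed=seed
        )
        labels.append(cmp.classification)
        starts.append(i0 / fs)
        if (
            recovery is None
            and len(labels) >= 2
            and labels[-1] == "no_effect"
            and labels[-2] == "no_effect"
        ):
            recovery = starts[-2]
        i0 += step
    return RecoveryResult(recovery, tuple(labels), tuple(starts))


def evaluate_compound(
    session: ScreenSession,
    roi_id: str,
    compound_index: int = 0,
    degree: int = DEFAULT_DEGREE,
    spectrum_window: str = "rect",
    window_s: float = DEFAULT_WINDOW_S,
    step_s: float = DEFAULT_STEP_S,
    transition_guard_s: float = DEFAULT_TRANSITION_GUARD_S,
    seed: int = 0,
) -> CompoundEffectReport:
    """Analyze one heart's response to the ``compound_index``-th compound.

    Runs detrending, spectra and beat metrics on the baseline and compound
    segments, classifies the spectral comparison, and — when a wash segment
    follows — detects baseline recovery.  The first ``transition_guard_s``
    seconds of the compound and wash segments are discarded (mixing
    transition).  Vehicle-control (solvent-only) compound segments are
    flagged ``is_control``.
    """
    baselines = [s for s in session.segments if s.label == "baseline"]
    compounds = [s for s in session.segments if s.label == "compound"]
    if not compounds:
        raise ProtocolError("session has no compound segment to evaluate")
    if compound_index >= len(compounds):
        raise ProtocolError(
            f"compound_index {compound_index} out of range ({len(compounds)} segments)"
        )
    base_seg = baselines[0]
    if base_seg.duration_s < MIN_BASELINE_S:
        raise InsufficientDataError(
            f"baseline of {base_seg.duration_s:.1f} s is shorter than "
            f"{MIN_BASELINE_S:.0f} s"
        )
    comp_seg = compounds[compound_index]
    wash_seg = next(
        (
            s
            for s in session.segments
            if s.label == "wash" and s.start_s >= comp_seg.end_s - 1e-9
        ),
        None,
    )

    guard = min(transition_guard_s, 0.25 * comp_seg.duration_s)
    comp_view = Segment(
        comp_seg.label, comp_seg.start_s + guard, comp_seg.end_s, comp_seg.compound
    )
    base_dt = detrend_normalize(session.segment_trace(base_seg, roi_id), degree)
    comp_dt = detrend_normalize(session.segment_trace(comp_view, roi_id), degree)
    base_spec = power_spectrum(base_dt, spectrum_window)
    comp_spec = power_spectrum(comp_dt, spectrum_window)
    comparison = compare_spectra(base_spec, comp_spec, base_dt, seed=seed)

    base_beats = detect_beats(base_dt)
    f_hint = base_beats.mean_rate_bpm / 60.0 if base_beats.mean_rate_bpm else None
    comp_beats = detect_beats(comp_dt, f_hint_hz=f_hint)

    wash_beats = None
    recovery = None
    if wash_seg is not None:
        wash_guard = min(transition_guard_s, 0.25 * wash_seg.duration_s)
        wash_view = Segment(wash_seg.label, wash_seg.start_s + wash_guard, wash_seg.end_s)
        wash_trace = session.segment_trace(wash_view, roi_id)
        try:
            rec = detect_recovery(
                base_dt,
                wash_trace,
                window_s=window_s,
                step_s=step_s,
                degree=degree,
                spectrum_window=spectrum_window,
                seed=seed,
            )
            # report times relative to the true wash start
            recovery = RecoveryResult(
                None if rec.recovery_time_s is None else rec.recovery_time_s + wash_guard,
                rec.window_labels,
                tuple(s + wash_guard for s in rec.window_starts_s),
            )
        except InsufficientDataError:
            recovery = None
        wash_dt = detrend_normalize(wash_trace, degree)
        wash_beats = detect_beats(wash_dt, f_hint_hz=f_hint)

    compound = comp_seg.compound
    return CompoundEffectReport(
        roi_id=roi_id,
        compound=compound,
        is_control=bool(compound and compound.is_vehicle_control),
        comparison=comparison,
        baseline_beats=base_beats,
        compound_beats=comp_beats,
        wash_beats=wash_beats,
        recovery=recovery,
        baseline_spectrum=base_spec,
        compound_spectrum=comp_spec,
        metadata={
            "fs_hz": session.table.fs_hz,
            "degree": degree,
            "spectrum_window": spectrum_window,
            "baseline_s": [base_seg.start_s, base_seg.end_s],
            "compound_s": [comp_seg.start_s, comp_seg.end_s],
            "wash_s": None if wash_seg is None else [wash_seg.start_s, wash_seg.end_s],
        },
    )


def run_screen(config: Mapping | str | Path, out_path: str | Path | None = None) -> dict:
    """Batch driver: evaluate every heart of every dish listed in a config.

    Config layout (JSON file or mapping)::

        {"fs_hz": 5.0,
         "dishes": [{"id": "dish1",
                     "traces": "dish1.dat",          # or "movie" + "rois"
                     "events": [{"time_s": 60, "action": "add_compound",
                                 "compound": {"name": "clofilium",
                                              "concentration_um": 10.0}},
                                {"time_s": 180, "action": "start_wash"}],
                     "degree": 2}]}

    Returns ``{"ok": bool, "dishes": [...]}`` with one entry per dish and one
    per-heart report (or recorded error) per ROI; a partial failure of one
    heart never blocks the others.  Deterministic given identical inputs.
    """
    if not isinstance(config, Mapping):
        cfg_path = Path(config)
        config = json.loads(cfg_path.read_text())
        base_dir = cfg_path.parent
    else:
        base_dir = Path(".")
    fs_hz = float(config.get("fs_hz", 5.0))
    out: dict = {"schema_version": REPORT_SCHEMA_VERSION, "ok": True, "dishes": []}
    for dish_cfg in config.get("dishes", []):
        dish_id = dish_cfg.get("id", "dish")
        degree = int(dish_cfg.get("degree", DEFAULT_DEGREE))
        entry: dict = {"id": dish_id, "hearts": {}, "errors": {}}
        try:
            if "traces" in dish_cfg:
                table = read_trace_table(base_dir / dish_cfg["traces"])
            else:
                stack = read_movie(base_dir / dish_cfg["movie"], fs_hz)
                rois = read_rois(base_dir / dish_cfg["rois"])
                table = extract_traces(stack, rois)
            session = segment_session(table, dish_cfg.get("events", []))
        except (CardiospecError, OSError, KeyError) as exc:
            entry["errors"]["dish"] = f"{type(exc).__name__}: {exc}"
            out["ok"] = False
            out["dishes"].append(entry)
            continue
        for roi_id in session.roi_ids:
            try:
                report = evaluate_compound(session, roi_id, degree=degree)
                entry["hearts"][roi_id] = report.to_dict()
            except CardiospecError as exc:
                entry["errors"][roi_id] = f"{type(exc).__name__}: {exc}"
                out["ok"] = False
        out["dishes"].append(entry)
    if out_path is not None:
        write_json_report(out, out_path)
    return out
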