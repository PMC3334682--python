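"""Session segmentation, washout recovery, compound evaluation, batch driver."""

import dataclasses
import json
import math

import numpy as np
import pytest

from cardiospec.errors import (
    InsufficientDataError,
    InvalidParameterError,
    ProtocolError,
)
from cardiospec.movie_io import TraceTable, write_trace_table
from cardiospec.preprocess import detrend_normalize
from cardiospec.screening import (
    CompoundRecord,
    SessionEvent,
    detect_recovery,
    evaluate_compound,
    run_screen,
    segment_session,
)
from cardiospec.synthetic_dish import (
    ContractionModel,
    SegmentSpec,
    default_dish,
    noise_sd_for_snr,
    simulate_session,
)

BASE = ContractionModel(beat_freq_hz=1.0, ibi_jitter_cv=0.05)
SNR5_SD = noise_sd_for_snr(ContractionModel(beat_freq_hz=1.0), 5.0)


def make_session(protocol, n_hearts=1, seed=0, noise_sd=SNR5_SD):
    dish = default_dish(n_hearts=n_hearts, seed=seed, contraction=BASE)
    sim = simulate_session(dish, protocol, render="trace", trace_noise_sd=noise_sd)
    return segment_session(sim.table, sim.events), sim


def drug_protocol(override, wash_s=None, wash_tau_s=None, name="X", base_s=120.0,
                  comp_s=120.0):
    prot = [
        SegmentSpec("baseline", base_s),
        SegmentSpec("compound", comp_s, override=override, compound_name=name,
                    concentration_um=10.0),
    ]
    if wash_s:
        prot.append(SegmentSpec("wash", wash_s, wash_tau_s=wash_tau_s))
    return prot


class TestSegmentSession:
    def _table(self, duration_s=400.0, fs=5.0):
        n = int(duration_s * fs)
        rng = np.random.default_rng(0)
        return TraceTable.from_traces(
            np.arange(n) / fs, {"h1": rng.normal(500, 5, n)}
        )

    def test_flowchart_slicing(self):
        table = self._table()
        clof = CompoundRecord("clofilium", 10.0)
        session = segment_session(
            table,
            [
                SessionEvent(60.0, "add_compound", clof),
                SessionEvent(180.0, "start_wash"),
            ],
        )
        labels = [(s.label, s.start_s, s.end_s) for s in session.segments]
        assert labels == [
            ("baseline", 0.0, 60.0),
            ("compound", 60.0, 180.0),
            ("wash", 180.0, 400.0),
        ]
        assert session.segments[1].compound == clof

    def test_empty_log_is_single_baseline(self):
        session = segment_session(self._table(), [])
        assert [s.label for s in session.segments] == ["baseline"]

    def test_compound_at_time_zero_rejected(self):
        with pytest.raises(ProtocolError, match="control reading"):
            segment_session(
                self._table(),
                [SessionEvent(0.0, "add_compound", CompoundRecord("x", 10.0))],
            )

    def test_out_of_order_events_rejected(self):
        with pytest.raises(ProtocolError, match="overlap"):
            segment_session(
                self._table(),
                [
                    SessionEvent(100.0, "add_compound", CompoundRecord("x", 10.0)),
                    SessionEvent(100.0, "start_wash"),
                ],
            )

    def test_wash_without_compound_rejected(self):
        with pytest.raises(ProtocolError, match="start_wash"):
            segment_session(self._table(), [SessionEvent(60.0, "start_wash")])

    def test_consecutive_compounds_without_wash_rejected(self):
        with pytest.raises(ProtocolError, match="add_compound"):
            segment_session(
                self._table(),
                [
                    SessionEvent(60.0, "add_compound", CompoundRecord("x", 10.0)),
                    SessionEvent(120.0, "add_compound", CompoundRecord("y", 10.0)),
                ],
            )

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(InvalidParameterError):
            CompoundRecord("x", 0.0)

    def test_event_dicts_accepted(self):
        session = segment_session(
            self._table(),
            [{"time_s": 60.0, "action": "add_compound",
              "compound": {"name": "x", "concentration_um": 10.0}}],
        )
        assert session.segments[1].label == "compound"


class TestDetectRecovery:
    def test_identical_statistics_recover_at_first_window(self):
        session, _ = make_session(drug_protocol(None, wash_s=240.0, name="DMSO"))
        base = detrend_normalize(
            session.segment_trace(session.segments[0], "heart1"), 2
        )
        wash = session.segment_trace(session.segments[2], "heart1")
        result = detect_recovery(base, wash)
        assert result.recovered
        assert result.recovery_time_s == 0.0

    def test_wash_too_short_rejected(self):
        session, _ = make_session(drug_protocol(None, wash_s=240.0))
        base = detrend_normalize(
            session.segment_trace(session.segments[0], "heart1"), 2
        )
        wash = session.segment_trace(session.segments[2], "heart1")
        from cardiospec.movie_io import IntensityTrace

        short = IntensityTrace(wash.values[:200], wash.fs_hz)
        with pytest.raises(InsufficientDataError):
            detect_recovery(base, short)

    @pytest.mark.parametrize("tau_s", [10.0, 60.0])
    def test_exponential_washout_matches_closed_form(self, tau_s):
        # window's dominant bin realigns once the mid-window frequency is
        # within half a classification bin of baseline
        over = dataclasses.replace(BASE, beat_freq_hz=1.5)
        detected = []
        for seed in range(3):
            session, _ = make_session(
                drug_protocol(over, wash_s=300.0, wash_tau_s=tau_s), seed=seed
            )
            rep = evaluate_compound(session, "heart1")
            assert rep.recovery is not None and rep.recovery.recovered
            detected.append(rep.recovery.recovery_time_s)
        predicted = max(0.0, tau_s * math.log(0.5 / 0.05) - 15.0)
        assert abs(np.mean(detected) - predicted) <= 30.0

    def test_recovery_monotone_in_time_constant(self):
        over = dataclasses.replace(BASE, beat_freq_hz=1.5)
        means = []
        for tau in (10.0, 30.0, 60.0):
            vals = []
            for seed in range(3):
                session, _ = make_session(
                    drug_protocol(over, wash_s=300.0, wash_tau_s=tau), seed=seed
                )
                rep = evaluate_compound(session, "heart1")
                vals.append(rep.recovery.recovery_time_s)
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]

    def test_persistent_arrest_never_recovers(self):
        arrested = dataclasses.replace(BASE, arrest_after_s=0.0)
        prot = [
            SegmentSpec("baseline", 120.0),
            SegmentSpec("compound", 120.0, override=arrested, compound_name="X",
                        concentration_um=10.0),
            SegmentSpec("wash", 240.0, override=arrested),
        ]
        session, _ = make_session(prot)
        rep = evaluate_compound(session, "heart1")
        assert rep.recovery is not None
        assert not rep.recovery.recovered


class TestEvaluateCompound:
    def test_dmso_control_flagged_and_no_effect(self):
        session, _ = make_session(drug_protocol(None, name="DMSO"))
        rep = evaluate_compound(session, "heart1")
        assert rep.is_control
        assert rep.classification == "no_effect"

    def test_herg_blocker_like_disruption_detected(self):
        # frequency + regularity disruption, clofilium-style
        over = dataclasses.replace(BASE, beat_freq_hz=1.6, ibi_jitter_cv=0.25)
        session, _ = make_session(drug_protocol(over, name="clofilium"))
        rep = evaluate_compound(session, "heart1")
        assert rep.classification != "no_effect"
        assert not rep.is_control
        # the report carries both spectra
        d = rep.to_dict()
        assert d["spectra"]["baseline"]["power"]
        assert d["spectra"]["compound"]["power"]

    def test_contraction_suppression_detected(self):
        # blebbistatin-style: amplitude to 5%, frequency unchanged
        over = dataclasses.replace(BASE, amplitude_frac=BASE.amplitude_frac * 0.05)
        session, _ = make_session(drug_protocol(over, name="blebbistatin"))
        rep = evaluate_compound(session, "heart1")
        assert rep.classification in ("amplitude_change", "arrest")

    def test_short_baseline_rejected(self):
        session, _ = make_session(drug_protocol(None, base_s=20.0))
        with pytest.raises(InsufficientDataError, match="baseline"):
            evaluate_compound(session, "heart1")

    def test_no_compound_segment_rejected(self):
        session, _ = make_session([SegmentSpec("baseline", 120.0)])
        with pytest.raises(ProtocolError):
            evaluate_compound(session, "heart1")


class TestRunScreen:
    def _write_config(self, tmp_path, n_hearts=3, corrupt_roi=None):
        dish = default_dish(n_hearts=n_hearts, seed=1, contraction=BASE)
        sim = simulate_session(
            dish, drug_protocol(None, name="DMSO"), render="trace",
            trace_noise_sd=SNR5_SD,
        )
        table = sim.table
        if corrupt_roi:
            table.data.loc[3, corrupt_roi] = np.nan
        write_trace_table(table, tmp_path / "dish1.dat")
        cfg = {
            "fs_hz": 5.0,
            "dishes": [
                {
                    "id": "dish1",
                    "traces": "dish1.dat",
                    "events": [
                        {"time_s": 120.0, "action": "add_compound",
                         "compound": {"name": "DMSO", "concentration_um": 10.0}}
                    ],
                }
            ],
        }
        path = tmp_path / "screen.json"
        path.write_text(json.dumps(cfg))
        return path

    def test_one_report_per_heart(self, tmp_path):
        cfg = self._write_config(tmp_path, n_hearts=3)
        report = run_screen(cfg)
        assert report["ok"]
        assert sorted(report["dishes"][0]["hearts"]) == ["heart1", "heart2", "heart3"]

    def test_reports_byte_identical_across_runs(self, tmp_path):
        cfg = self._write_config(tmp_path)
        run_screen(cfg, tmp_path / "a.json")
        run_screen(cfg, tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_partial_failure_keeps_other_hearts(self, tmp_path):
        cfg = self._write_config(tmp_path, n_hearts=3, corrupt_roi="heart2")
        report = run_screen(cfg)
        assert not report["ok"]
        dish = report["dishes"][0]
        assert set(dish["hearts"]) == {"heart1", "heart3"}
        assert "heart2" in dish["errors"]
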