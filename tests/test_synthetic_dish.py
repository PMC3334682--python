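"""Generator tests: beat schedules, rendering, calcium traces, sessions."""

import numpy as np
import pytest
from scipy import stats

from cardiospec.errors import GeometryError, InvalidParameterError, ProtocolError
from cardiospec.synthetic_dish import (
    CalciumSimConfig,
    ContractionModel,
    DishConfig,
    HeartGeometry,
    SegmentSpec,
    default_dish,
    make_beat_schedule,
    render_heart_movie,
    simulate_calcium_trace,
    simulate_session,
)


class TestBeatSchedule:
    def test_regular_schedule_is_exact(self):
        m = ContractionModel(beat_freq_hz=1.0, ibi_jitter_cv=0.0, skip_prob=0.0)
        sched = make_beat_schedule(m, 10.0, seed=0)
        assert len(sched.realized_times) == 10
        np.testing.assert_allclose(sched.realized_times, 0.5 + np.arange(10))
        np.testing.assert_allclose(np.diff(sched.realized_times), 1.0)

    def test_all_beats_skipped(self):
        m = ContractionModel(beat_freq_hz=1.0, skip_prob=1.0)
        sched = make_beat_schedule(m, 10.0, seed=0)
        assert sched.realized_times.size == 0
        assert sched.scheduled_times.size > 0

    def test_skip_count_matches_bernoulli_oracle(self):
        # independent re-simulation drawing the same Bernoulli stream
        m = ContractionModel(beat_freq_hz=1.0, ibi_jitter_cv=0.0, skip_prob=0.2)
        seed = 42
        sched = make_beat_schedule(m, 600.0, seed=seed)
        n_sched = sched.scheduled_times.size
        oracle_keep = np.random.default_rng(seed).random(n_sched) >= 0.2
        expected = sched.scheduled_times[oracle_keep]
        np.testing.assert_array_equal(sched.realized_times, expected)
        # realized count within the binomial 99% interval
        lo = stats.binom.ppf(0.005, n_sched, 0.8)
        hi = stats.binom.ppf(0.995, n_sched, 0.8)
        assert lo <= sched.realized_times.size <= hi

    def test_arrest_truncates_schedule(self):
        m = ContractionModel(beat_freq_hz=1.0, arrest_after_s=5.0)
        sched = make_beat_schedule(m, 20.0, seed=0)
        assert sched.scheduled_times.max() <= 5.0

    def test_jittered_gaps_have_requested_cv(self):
        m = ContractionModel(beat_freq_hz=1.0, ibi_jitter_cv=0.2)
        sched = make_beat_schedule(m, 3000.0, seed=1)
        gaps = np.diff(sched.realized_times)
        assert gaps.mean() == pytest.approx(1.0, abs=0.02)
        assert gaps.std() / gaps.mean() == pytest.approx(0.2, abs=0.02)

    def test_times_strictly_increasing_and_bounded(self):
        m = ContractionModel(beat_freq_hz=2.0, ibi_jitter_cv=0.3, skip_prob=0.1)
        sched = make_beat_schedule(m, 60.0, seed=3)
        assert np.all(np.diff(sched.scheduled_times) > 0)
        assert sched.scheduled_times.min() >= 0
        assert sched.scheduled_times.max() <= 60.0
        # realized is a subset of scheduled
        assert np.isin(sched.realized_times, sched.scheduled_times).all()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            ContractionModel(beat_freq_hz=0.0)
        with pytest.raises(InvalidParameterError):
            ContractionModel(skip_prob=1.5)
        with pytest.raises(InvalidParameterError):
            ContractionModel(amplitude_frac=1.0)
        with pytest.raises(InvalidParameterError):
            make_beat_schedule(ContractionModel(), -1.0, seed=0)


class TestRendering:
    def test_static_scene_gives_identical_frames(self):
        m = ContractionModel(amplitude_frac=0.0)
        dish = default_dish(n_hearts=2, seed=0, contraction=m, noise_sd=0.0,
                            duration_s=5.0)
        stack, _ = render_heart_movie(dish)
        assert np.all(stack.frames == stack.frames[0])

    def test_linear_drift_slope_recovered(self):
        m = ContractionModel(amplitude_frac=0.0)
        c1 = 0.73
        dish = default_dish(
            n_hearts=1, seed=0, contraction=m, noise_sd=0.0,
            drift_coeffs=(0.0, c1), duration_s=30.0,
        )
        stack, _ = render_heart_movie(dish)
        means = stack.frames.mean(axis=(1, 2))
        slope = np.polyfit(stack.times, means, 1)[0]
        assert slope == pytest.approx(c1, abs=1e-9)

    def test_frame_count_convention(self):
        dish = default_dish(n_hearts=1, seed=0, duration_s=10.3, fs_hz=5.0)
        stack, _ = render_heart_movie(dish)
        assert stack.n_frames == round(5.0 * 10.3)
        assert stack.times[0] == 0.0

    def test_heart_outside_frame_raises(self):
        dish = DishConfig(
            hearts=(HeartGeometry(center=(5.0, 48.0), semi_axes=(10.0, 8.0)),),
            contractions=(ContractionModel(),),
            seed=0,
        )
        with pytest.raises(GeometryError):
            render_heart_movie(dish)

    def test_seeded_determinism_bit_identical(self):
        a, ta = render_heart_movie(default_dish(n_hearts=3, seed=11, duration_s=10.0))
        b, tb = render_heart_movie(default_dish(n_hearts=3, seed=11, duration_s=10.0))
        assert np.array_equal(a.frames, b.frames)
        for ha, hb in zip(ta.hearts, tb.hearts):
            np.testing.assert_array_equal(ha.realized_times, hb.realized_times)

    def test_equal_phase_frames_identical_without_noise(self):
        # deterministic 1 Hz schedule at 5 Hz sampling repeats every 5 frames
        m = ContractionModel(beat_freq_hz=1.0, ibi_jitter_cv=0.0)
        dish = default_dish(n_hearts=2, seed=0, contraction=m, noise_sd=0.0,
                            duration_s=20.0)
        stack, _ = render_heart_movie(dish)
        f = stack.frames
        assert np.array_equal(f[7], f[12])
        assert np.array_equal(f[10], f[15])


class TestCalcium:
    def test_quiet_trace_is_constant_baseline(self):
        cfg = CalciumSimConfig(seed=0, spontaneous_rate_hz=0.0, duration_s=200.0)
        trace, truth = simulate_calcium_trace(cfg)
        assert np.all(trace.values == cfg.baseline_f0)
        assert truth.event_times.size == 0

    def test_single_forced_event_peaks_at_onset_sample(self):
        cfg = CalciumSimConfig(
            seed=0, spontaneous_rate_hz=0.0, duration_s=400.0,
            forced_events=((100.3, 0.5),),
        )
        trace, truth = simulate_calcium_trace(cfg)
        i_on = int(np.ceil(100.3 * cfg.fs_hz))
        assert trace.values.max() == pytest.approx(cfg.baseline_f0 * 1.5)
        assert int(np.argmax(trace.values)) == i_on
        assert truth.event_times[0] == i_on / cfg.fs_hz

    def test_poisson_count_matches_oracle_redraw(self):
        cfg = CalciumSimConfig(seed=7, spontaneous_rate_hz=0.02, duration_s=1200.0)
        _, truth = simulate_calcium_trace(cfg)
        rng = np.random.default_rng(7)
        t, count = rng.exponential(50.0), 0
        while t < 1200.0:
            count += 1
            t += rng.exponential(50.0)
        assert truth.event_times.size == count

    def test_determinism(self):
        cfg = CalciumSimConfig(seed=5, noise_sd=20.0)
        a, _ = simulate_calcium_trace(cfg)
        b, _ = simulate_calcium_trace(cfg)
        assert np.array_equal(a.values, b.values)


class TestSession:
    def test_protocol_must_start_with_baseline(self):
        dish = default_dish(n_hearts=1, seed=0)
        with pytest.raises(ProtocolError):
            simulate_session(dish, [SegmentSpec("compound", 60.0)])

    def test_frequency_override_steps_at_boundary(self):
        base = ContractionModel(beat_freq_hz=1.0, ibi_jitter_cv=0.0)
        over = ContractionModel(beat_freq_hz=1.5, ibi_jitter_cv=0.0)
        dish = default_dish(n_hearts=1, seed=0, contraction=base)
        sim = simulate_session(
            dish,
            [SegmentSpec("baseline", 60.0), SegmentSpec("compound", 60.0, override=over)],
            render="trace",
            trace_noise_sd=0.0,
        )
        truth = sim.truth.hearts[0]
        t = truth.realized_times
        base_gaps = np.diff(t[t < 59.0])
        comp_gaps = np.diff(t[t > 61.0])
        np.testing.assert_allclose(base_gaps, 1.0, atol=1e-9)
        np.testing.assert_allclose(comp_gaps, 1.0 / 1.5, atol=1e-9)

    def test_baseline_only_statistics_match_plain_render(self):
        base = ContractionModel(beat_freq_hz=1.0)
        dish = default_dish(n_hearts=2, seed=4, contraction=base)
        sim = simulate_session(dish, [SegmentSpec("baseline", 120.0)], render="trace")
        sched = make_beat_schedule(base, 120.0, np.random.default_rng(
            np.random.SeedSequence(4).spawn(3)[0]))
        np.testing.assert_array_equal(sim.truth.hearts[0].realized_times,
                                      sched.realized_times)

    def test_event_log_written_at_segment_boundaries(self):
        dish = default_dish(n_hearts=1, seed=0)
        sim = simulate_session(
            dish,
            [
                SegmentSpec("baseline", 60.0),
                SegmentSpec("compound", 60.0, compound_name="clofilium",
                            concentration_um=10.0),
                SegmentSpec("wash", 60.0, wash_tau_s=10.0),
            ],
            render="trace",
        )
        assert sim.events[0] == {
            "time_s": 60.0, "action": "add_compound",
            "compound": {"name": "clofilium", "concentration_um": 10.0,
                         "solvent": "DMSO"},
        }
        assert sim.events[1]["action"] == "start_wash"
        assert [s[0] for s in sim.truth.segments] == ["baseline", "compound", "wash"]

    def test_wash_relaxation_ground_truth_parameters(self):
        base = ContractionModel(beat_freq_hz=1.0)
        over = ContractionModel(beat_freq_hz=1.5)
        dish = default_dish(n_hearts=1, seed=0, contraction=base)
        sim = simulate_session(
            dish,
            [
                SegmentSpec("baseline", 60.0),
                SegmentSpec("compound", 60.0, override=over),
                SegmentSpec("wash", 120.0, wash_tau_s=20.0),
            ],
            render="trace",
        )
        relax = sim.truth.wash_relaxations[0]
        assert relax["f_from"] == 1.5
        assert relax["f_to"] == 1.0
        assert relax["tau_s"] == 20.0
        assert relax["start_s"] == 120.0

    def test_trace_mode_determinism(self):
        dish = default_dish(n_hearts=3, seed=9)
        prot = [SegmentSpec("baseline", 60.0)]
        a = simulate_session(dish, prot, render="trace")
        b = simulate_session(dish, prot, render="trace")
        assert a.table.data.equals(b.table.data)
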