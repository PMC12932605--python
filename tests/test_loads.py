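"""Load-processing tests: filter gains, 50 N segmentation, matching,
exclusion rules, time normalization and closed-form characteristic oracles."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from sslrun import loads, synth
from sslrun.loads import (
    CharacteristicConfig,
    DEFAULT_CHARACTERISTIC_CONFIGS,
    StepSample,
    apply_exclusions,
    filter_and_normalize_ssl,
    impulse,
    loading_rate,
    match_steps,
    peak,
    segment_steps_grf,
    time_normalize,
)

GRF_RATE = 1200.0


def _step(stance=0.30, step_dur=0.38, curves=None, acc=None):
    if curves is None:
        curves = np.tile(3.0 * np.sin(np.linspace(0, np.pi, 100)), (4, 1))
    if acc is None:
        acc = np.random.default_rng(0).standard_normal((6, 72))
    return StepSample(
        subject_id="S1",
        trial_id="S1_2.78",
        speed=2.78,
        stance_duration=stance,
        step_duration=step_dur,
        imu_matrix=np.zeros((12, 100)),
        ssl_curves=np.asarray(curves, dtype=float),
        acc_raw_segments=acc,
        acc_filt_segments=acc,
        gyro_segments=np.zeros((6, 71)),
        imu_rate=240.0,
    )


class TestFilterNormalize:
    def test_constant_input_normalized(self):
        out = filter_and_normalize_ssl(np.full(2000, 800.0), GRF_RATE, body_weight=800.0)
        np.testing.assert_allclose(out, 1.0, atol=1e-9)

    def test_body_weight_arithmetic(self):
        profile = synth.SubjectProfile("S", 79.8, "male", 24.0, 186.0, 31.0, 3.3)
        assert profile.body_weight == pytest.approx(79.8 * 9.81)
        assert profile.body_weight == pytest.approx(782.8, abs=0.05)

    def test_ripple_attenuation(self):
        """100 Hz ripple shrinks > 10x through the designed 20 Hz filter."""
        sos = sp_signal.butter(5, 20.0, btype="low", fs=GRF_RATE, output="sos")
        _, h = sp_signal.sosfreqz(sos, worN=[100.0], fs=GRF_RATE)
        assert abs(h[0]) < 0.1
        t = np.arange(3000) / GRF_RATE
        bump = 1000.0 * np.exp(-0.5 * ((t - 1.25) / 0.05) ** 2)
        ripple = 100.0 * np.sin(2 * np.pi * 100 * t)
        out = filter_and_normalize_ssl(bump + ripple, GRF_RATE, 800.0)
        clean = filter_and_normalize_ssl(bump, GRF_RATE, 800.0)
        assert np.abs(out - clean).max() < (100.0 / 800.0) / 10

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            filter_and_normalize_ssl(np.ones(100), GRF_RATE, body_weight=0.0)
        with pytest.raises(ValueError):
            filter_and_normalize_ssl(np.ones(100), rate=30.0, body_weight=700.0)


class TestSegmentation:
    def test_rectangular_pulse_half_open(self):
        v = np.zeros(1000)
        v[100:400] = 600.0
        assert segment_steps_grf(v, GRF_RATE) == [(100, 400)]

    def test_zero_signal_gives_no_steps(self):
        assert segment_steps_grf(np.zeros(500), GRF_RATE) == []

    def test_chatter_discarded(self):
        v = np.zeros(1000)
        v[100:400] = 600.0
        v[500:505] = 600.0  # 4.2 ms blip
        assert segment_steps_grf(v, GRF_RATE) == [(100, 400)]

    def test_matches_generator_truth_within_one_sample(self, small_cohort):
        _cfg, _subjects, trials = small_cohort
        trial = trials[0]
        segs = segment_steps_grf(trial.vgrf, trial.grf_rate)
        assert len(segs) == len(trial.steps)
        for (ic, to), st in zip(segs, trial.steps):
            assert abs((to - ic) - st.stance_duration * trial.grf_rate) <= 1


class TestMatching:
    def test_identical_sets_fully_matched(self):
        t = np.array([0.5, 1.2, 1.9])
        matches, unmatched = match_steps(t, t)
        assert matches == [(0, 0), (1, 1), (2, 2)]
        assert unmatched == []

    def test_out_of_tolerance_step_excluded(self):
        matches, unmatched = match_steps(np.array([0.5, 1.2]), np.array([0.5, 1.35]))
        assert matches == [(0, 0)]
        assert unmatched == [1]

    def test_jittered_events_all_matched(self, rng):
        t = np.arange(20) * 0.7
        jitter = rng.uniform(-0.02, 0.02, size=20)
        matches, unmatched = match_steps(t, t + jitter)
        assert len(matches) == 20 and not unmatched
        # greedy nearest matching equals identity pairing here
        assert all(i == j for i, j in matches)


class TestExclusions:
    def test_long_stance_rejected(self):
        s = apply_exclusions(_step(stance=0.55))
        assert not s.accepted and s.exclusion_reason == "stance_duration"

    def test_clean_step_accepted(self):
        s = apply_exclusions(_step(stance=0.30, step_dur=0.40))
        assert s.accepted and s.exclusion_reason is None

    @pytest.mark.parametrize(
        "stance,step_dur,reason",
        [
            (0.10, 0.40, "stance_duration"),
            (0.30, 0.65, "step_duration"),
            (0.30, 0.15, "step_duration"),
        ],
    )
    def test_duration_rules(self, stance, step_dur, reason):
        s = apply_exclusions(_step(stance=stance, step_dur=step_dur))
        assert s.exclusion_reason == reason

    def test_dropout_detected_in_raw_channel(self):
        acc = np.random.default_rng(0).standard_normal((6, 72))
        acc[3, 10:35] = 0.0
        s = apply_exclusions(_step(acc=acc))
        assert s.exclusion_reason == "corruption"

    def test_load_out_of_range(self):
        curves = np.tile(20.0 * np.sin(np.linspace(0, np.pi, 100)), (4, 1))
        s = apply_exclusions(_step(curves=curves))
        assert s.exclusion_reason == "ssl_range"
        curves = np.tile(0.3 * np.sin(np.linspace(0, np.pi, 100)), (4, 1))
        assert apply_exclusions(_step(curves=curves)).exclusion_reason == "ssl_range"

    def test_first_failing_rule_wins_and_idempotent(self):
        # violates stance duration AND dropout: stance reported first
        acc = np.zeros((6, 72))
        s = _step(stance=0.6, acc=acc)
        for _ in range(3):
            s = apply_exclusions(s)
            assert s.exclusion_reason == "stance_duration"

    def test_generator_artifacts_get_expected_reasons(self):
        cfg = synth.GeneratorConfig(
            n_subjects=2, speeds=(2.78,), corrupt_fraction=0.5, seed=17
        )
        subjects, trials = synth.generate_cohort(cfg, n_steps_per_trial=15)
        profiles = {s.subject_id: s for s in subjects}
        expected = {
            "dropout": "corruption",
            "stance_inflation": "stance_duration",
            "ssl_out_of_range": "ssl_range",
        }
        n_checked = 0
        for trial in trials:
            truth = {s.index: s for s in trial.steps}
            for st in loads.build_step_samples(trial, profiles[trial.subject_id]):
                t = truth.get(st.truth_index)
                if t is None or not t.has_next or not t.corrupted:
                    continue
                assert st.exclusion_reason == expected[t.artifact]
                n_checked += 1
        assert n_checked >= 8


class TestTimeNormalize:
    def test_constant_curve(self):
        np.testing.assert_allclose(time_normalize(np.full(73, 2.5)), 2.5)

    def test_linear_ramp_exact(self):
        out = time_normalize(np.linspace(0, 1, 73))
        np.testing.assert_allclose(out, np.linspace(0, 1, 100), atol=1e-12)

    def test_round_trip_identity(self):
        x = np.random.default_rng(3).standard_normal(100)
        np.testing.assert_allclose(time_normalize(x), x, atol=1e-12)

    def test_endpoints_preserved(self):
        x = np.random.default_rng(4).standard_normal(57)
        out = time_normalize(x)
        assert out[0] == x[0] and out[-1] == x[-1]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            time_normalize(np.array([1.0]))


class TestCharacteristics:
    def test_peak_of_template(self):
        tau = 44 / 99  # lies exactly on the 100-point sampling grid
        curve = 4.2 * synth.raised_cosine(np.linspace(0, 1, 100), tau)
        value, idx = peak(curve)
        assert value == pytest.approx(4.2, abs=1e-9)
        assert idx == 44

    def test_peak_monotone_curve_and_ties(self):
        value, idx = peak(np.linspace(0, 1, 100))
        assert (value, idx) == (1.0, 99)
        value, idx = peak(np.array([0.0, 2.0, 2.0, 1.0]))
        assert idx == 1  # earliest tie

    def test_impulse_closed_form(self):
        assert impulse(np.full(100, 2.0), 0.25) == pytest.approx(0.5)
        assert impulse(np.zeros(100), 0.3) == 0.0

    def test_impulse_template_matches_analytic_integral(self):
        """Raised-cosine template integral is A * stance / 2 exactly."""
        for tau in (0.3, 0.45, 0.6):
            curve = 5.0 * synth.raised_cosine(np.linspace(0, 1, 100), tau)
            assert impulse(curve, 0.28) == pytest.approx(5.0 * 0.28 / 2, rel=0.02)

    def test_impulse_linearity(self):
        curve = np.random.default_rng(5).uniform(0, 3, 100)
        assert impulse(3.0 * curve, 0.3) == pytest.approx(3.0 * impulse(curve, 0.3))
        assert impulse(curve, 0.6) == pytest.approx(2.0 * impulse(curve, 0.3))

    def test_loading_rate_linear_closed_form(self):
        curve = np.concatenate([np.linspace(0, 1, 51), np.linspace(1, 0, 50)[1:]])
        cfg = DEFAULT_CHARACTERISTIC_CONFIGS["achilles"]
        # peak frame 50; frames 10 and 40 hold 0.2 and 0.8 BW; dt = 30/(100/0.3)
        assert loading_rate(curve, 0.3, cfg) == pytest.approx(6.667, abs=1e-3)

    def test_loading_rate_constant_curve_zero(self):
        cfg = DEFAULT_CHARACTERISTIC_CONFIGS["knee"]
        assert loading_rate(np.full(100, 2.0), 0.3, cfg) == 0.0

    def test_loading_rate_scales_inversely_with_stance(self):
        curve = np.concatenate([np.linspace(0, 1, 51), np.linspace(1, 0, 50)[1:]])
        cfg = DEFAULT_CHARACTERISTIC_CONFIGS["ankle"]
        assert loading_rate(curve, 0.15, cfg) == pytest.approx(
            2.0 * loading_rate(curve, 0.30, cfg)
        )

    def test_degenerate_early_peak_returns_none(self):
        curve = np.concatenate([[5.0], np.linspace(1, 0, 99)])
        cfg = DEFAULT_CHARACTERISTIC_CONFIGS["achilles"]
        assert loading_rate(curve, 0.3, cfg) is None

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CharacteristicConfig(0.8, 0.2, "ic_to_peak")
        with pytest.raises(ValueError):
            CharacteristicConfig(0.2, 0.8, "sideways")


class TestPipelineRecovery:
    def test_noiseless_pipeline_recovers_template_characteristics(self):
        """Peak and impulse from the full pipeline match the generator's
        analytic template values within rectangular-rule tolerance."""
        cfg = synth.GeneratorConfig(noise_scale=0.0, seed=23)
        sub = synth.SubjectProfile("S1", 75.0, "male", 25.0, 180.0, 30.0, 3.0)
        trial = synth.generate_trial(sub, 2.78, cfg, n_steps=6)
        steps = loads.build_step_samples(trial, sub)
        truth = {s.index: s for s in trial.steps}
        checked = 0
        for st in steps:
            t = truth.get(st.truth_index)
            if not st.accepted or t is None:
                continue
            for k, structure in enumerate(synth.STRUCTURES):
                pk, _ = peak(st.ssl_curves[k])
                assert pk == pytest.approx(t.amps[structure], rel=0.02)
                imp = impulse(st.ssl_curves[k], st.stance_duration)
                expected = t.amps[structure] * t.stance_duration / 2
                assert imp == pytest.approx(expected, rel=0.02)
            checked += 1
        assert checked >= 4

    def test_accepted_steps_nonnegative_and_100_samples(self, accepted_steps):
        _subjects, steps = accepted_steps
        assert len(steps) >= 40
        for st in steps:
            assert st.ssl_curves.shape == (4, 100)
            assert st.imu_matrix.shape == (12, 100)
            assert np.all(st.ssl_curves >= -0.01)
            assert 0.15 <= st.stance_duration <= 0.5
            assert 0.21 <= st.step_duration <= 0.6
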