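"""Evaluation-harness tests: fold construction and leakage, standardization
contracts, longhand metric oracles, MC dropout and channel ablation."""

import numpy as np
import pytest

from sslrun import evaluate, loads, models
from sslrun.evaluate import (
    Scalers,
    characteristic_metrics,
    curve_metrics,
    macro_average,
    make_folds,
    mc_dropout,
    standardize,
)
from sslrun.models import ModelData, ModelSpec


class TestFolds:
    def test_cohort_of_43_gives_balanced_folds(self):
        ids = [f"S{i:02d}" for i in range(43)]
        plan = make_folds(ids, k=5, seed=0)
        sizes = sorted(len(f) for f in plan.test_subjects)
        assert sizes == [8, 8, 9, 9, 9]

    def test_every_subject_tested_exactly_once(self):
        ids = [f"S{i:02d}" for i in range(17)]
        plan = make_folds(ids, k=5, seed=1)
        tested = [s for fold in plan.test_subjects for s in fold]
        assert sorted(tested) == sorted(ids)

    def test_train_val_test_disjoint_every_fold(self):
        ids = [f"S{i:02d}" for i in range(23)]
        plan = make_folds(ids, k=5, seed=2)
        for f in range(5):
            tr = set(plan.train_subjects[f])
            va = set(plan.val_subjects[f])
            te = set(plan.test_subjects[f])
            assert not (tr & va or tr & te or va & te)
            assert tr | va | te == set(ids)
            assert len(va) >= 1

    def test_same_seed_identical_plan(self):
        ids = [f"S{i}" for i in range(12)]
        a, b = make_folds(ids, seed=5), make_folds(ids, seed=5)
        assert a.test_subjects == b.test_subjects
        assert a.val_subjects == b.val_subjects

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b", "c"], k=5)


class TestStandardize:
    def _data(self, rng, n=40):
        return ModelData(
            x_ts=rng.normal(3.0, 2.0, size=(n, 100, 4)),
            x_tab=rng.normal(-1.0, 0.5, size=(n, 6)),
            y=rng.uniform(0, 5, size=(n, 100)),
        )

    def test_train_statistics_after_transform(self, rng):
        (tr, _), _ = standardize(self._data(rng), self._data(rng))
        np.testing.assert_allclose(tr.x_tab.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(tr.x_tab.std(axis=0), 1.0, atol=1e-6)
        np.testing.assert_allclose(tr.x_ts.mean(axis=(0, 1)), 0.0, atol=1e-10)
        np.testing.assert_allclose(tr.x_ts.std(axis=(0, 1)), 1.0, atol=1e-6)

    def test_test_set_uses_train_statistics(self, rng):
        train = self._data(rng)
        shifted = ModelData(
            x_ts=train.x_ts + 10.0, x_tab=train.x_tab + 10.0, y=train.y
        )
        (tr, te), sc = standardize(train, shifted)
        # a shifted copy transformed with *train* statistics keeps its offset
        assert te.x_tab.mean() > 5.0
        np.testing.assert_allclose(
            te.x_tab - tr.x_tab,
            np.broadcast_to(10.0 / sc.tab_std, te.x_tab.shape),
            atol=1e-10,
        )

    def test_zero_variance_feature_centred_not_divided(self, rng):
        train = self._data(rng)
        train.x_tab[:, 2] = 7.0
        (tr, _), sc = standardize(train, train)
        assert sc.tab_std[2] == 1.0
        np.testing.assert_allclose(tr.x_tab[:, 2], 0.0, atol=1e-12)

    def test_empty_training_rejected(self):
        empty = ModelData(x_ts=None, x_tab=None, y=np.zeros((0, 100)))
        with pytest.raises(ValueError):
            standardize(empty)

    def test_targets_left_in_body_weights(self, rng):
        train = self._data(rng)
        (tr, _), _ = standardize(train, train)
        np.testing.assert_array_equal(tr.y, train.y)


class TestCurveMetrics:
    def test_perfect_prediction(self, rng):
        y = rng.uniform(0.2, 4.0, size=(6, 100))
        m = curve_metrics(y, y)
        assert m == {"mse": 0.0, "mape": 0.0, "r2": 1.0}

    def test_pooled_mean_prediction_zero_r2(self, rng):
        y = rng.uniform(0.2, 4.0, size=(6, 100))
        m = curve_metrics(np.full_like(y, y.mean()), y)
        assert m["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_longhand_toy(self):
        truth = np.array([[1.0, 2.0, 3.0, 2.0], [0.05, 1.0, 2.0, 1.0]])
        pred = np.array([[1.5, 2.0, 2.0, 2.0], [0.05, 2.0, 2.0, 0.0]])
        # longhand: squared errors 0.25,0,1,0 / 0,1,0,1 -> mse = 3.25/8
        # MAPE over truth >= 0.1: |err|/truth for 7 entries
        # (0.5/1, 0, 1/3, 0, 1/1, 0, 1/1) -> mean * 100
        # R^2: pooled mean of truth = 12.05/8
        m = curve_metrics(pred, truth)
        assert m["mse"] == pytest.approx(3.25 / 8)
        expected_mape = 100 * (0.5 + 0.0 + 1 / 3 + 0.0 + 1.0 + 0.0 + 1.0) / 7
        assert m["mape"] == pytest.approx(expected_mape)
        mu = 12.05 / 8
        ss_tot = np.sum((truth - mu) ** 2)
        assert m["r2"] == pytest.approx(1 - 3.25 / ss_tot)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            curve_metrics(np.zeros((2, 100)), np.zeros((3, 100)))


class TestCharacteristicMetrics:
    def test_perfect_prediction_all_zero(self, rng):
        y = np.stack([3.0 * np.sin(np.linspace(0, np.pi, 100)) for _ in range(5)])
        sd = np.full(5, 0.3)
        out = characteristic_metrics(y, y, sd, "achilles")
        for ch in ("peak", "impulse", "loading_rate"):
            assert out[ch]["mse"] == 0.0
            assert out[ch]["mape"] == 0.0

    def test_constant_shift_closed_form(self):
        y = np.stack([2.0 + np.sin(np.linspace(0, np.pi, 100)) for _ in range(4)])
        sd = np.array([0.2, 0.25, 0.3, 0.35])
        out = characteristic_metrics(y + 0.5, y, sd, "achilles")
        assert out["peak"]["mse"] == pytest.approx(0.25, rel=1e-6)
        # impulse error is 0.5 * stance per step
        assert out["impulse"]["mse"] == pytest.approx(np.mean((0.5 * sd) ** 2), rel=1e-6)

    def test_degenerate_predicted_peak_counted(self):
        truth = np.stack([np.sin(np.linspace(0, np.pi, 100)) for _ in range(3)])
        pred = truth.copy()
        pred[0] = np.concatenate([[9.0], np.linspace(0.5, 0, 99)])  # peak at frame 0
        out = characteristic_metrics(pred, truth, np.full(3, 0.3), "achilles")
        assert out["loading_rate_excluded"] == 1


class TestMacroAverage:
    def test_unweighted_mean_over_folds(self):
        folds = [{"mse": 1.0, "r2": 0.9}, {"mse": 3.0, "r2": 0.7}]
        out = macro_average(folds)
        assert out == {"mse": 2.0, "r2": pytest.approx(0.8)}


def _trained_small_ts(seed=0, dropout=0.2, n=60):
    rng = np.random.default_rng(seed)
    amp = rng.uniform(1.0, 3.0, size=n)
    template = np.sin(np.linspace(0, np.pi, 100))
    x_ts = rng.normal(0, 0.05, size=(n, 100, 3))
    x_ts[:, :, 0] += amp[:, None] * template
    data = ModelData(x_ts=x_ts, x_tab=None, y=amp[:, None] * template)
    spec = ModelSpec(model_type="ts_lstm", dropout=dropout, learning_rate=3e-3,
                     max_epochs=25, patience=25, seed=seed)
    model = models.build(spec, ts_channels=3).fit(data, data)
    return model, data


class TestMcDropout:
    def test_sds_nonnegative_and_seeded(self):
        model, data = _trained_small_ts()
        sd = np.full(data.n, 0.3)
        est = mc_dropout(model, data, sd, "achilles", n_passes=30, seed=1)
        assert np.all(est.curve_sd >= 0.0)
        assert np.all(est.peak_sd >= 0.0)
        est2 = mc_dropout(model, data, sd, "achilles", n_passes=30, seed=1)
        np.testing.assert_array_equal(est.curve_sd, est2.curve_sd)

    def test_zero_dropout_rate_gives_exactly_zero_sd(self):
        model, data = _trained_small_ts(dropout=0.0)
        est = mc_dropout(model, data, np.full(data.n, 0.3), "achilles",
                         n_passes=10, seed=2)
        assert np.all(est.curve_sd == 0.0)
        assert np.all(est.peak_sd == 0.0)
        assert np.all(est.impulse_sd == 0.0)

    def test_model_without_dropout_layers_rejected(self):
        y = np.ones((4, 100))
        mean = models.MeanRegressor().fit(ModelData(x_ts=None, x_tab=None, y=y))
        with pytest.raises(ValueError):
            mc_dropout(mean, ModelData(x_ts=None, x_tab=None, y=y),
                       np.full(4, 0.3), "achilles")

    def test_two_seeds_agree_within_monte_carlo_error(self):
        model, data = _trained_small_ts()
        sd = np.full(data.n, 0.3)
        a = mc_dropout(model, data, sd, "achilles", n_passes=100, seed=3)
        b = mc_dropout(model, data, sd, "achilles", n_passes=100, seed=4)
        ma, mb = a.curve_sd.mean(), b.curve_sd.mean()
        assert abs(ma - mb) / max(ma, mb) < 0.3


class TestAblation:
    def test_informative_channel_matters_noise_channel_does_not(self):
        """Removing the channel that carries the generative signal hurts;
        removing a pure-noise channel does not."""
        rng = np.random.default_rng(8)
        n = 200
        amp = rng.uniform(0.5, 3.5, size=n)
        template = np.sin(np.linspace(0, np.pi, 100))
        x_ts = rng.normal(0, 0.05, size=(n, 100, 3))
        x_ts[:, :, 0] += amp[:, None] * template  # informative channel
        x_ts[:, :, 2] = rng.standard_normal((n, 100))  # irrelevant channel
        y = amp[:, None] * template
        tr = ModelData(x_ts=x_ts[:140], x_tab=None, y=y[:140])
        va = ModelData(x_ts=x_ts[140:170], x_tab=None, y=y[140:170])
        te = ModelData(x_ts=x_ts[170:], x_tab=None, y=y[170:])
        spec = ModelSpec(model_type="ts_lstm", learning_rate=1e-3,
                         max_epochs=80, patience=30, batch_size=32, seed=0)
        full = models.build(spec, ts_channels=3).fit(tr, va)
        r2_full = curve_metrics(full.predict(te), te.y)["r2"]
        r2_wo_noise = evaluate.ablate_channel(spec, 2, tr, va, te)["r2"]
        r2_wo_signal = evaluate.ablate_channel(spec, 0, tr, va, te)["r2"]
        assert r2_full > 0.9
        assert abs(r2_wo_noise - r2_full) < 0.05
        assert r2_wo_signal < 0.5
        assert r2_wo_signal < r2_wo_noise

    def test_invalid_requests_rejected(self):
        data = ModelData(x_ts=np.zeros((4, 100, 6)), x_tab=None, y=np.zeros((4, 100)))
        spec = ModelSpec(model_type="ts_lstm")
        with pytest.raises(ValueError):
            evaluate.ablate_channel(spec, 6, data, data, data)
        with pytest.raises(ValueError):
            evaluate.ablate_channel(ModelSpec(model_type="f_nn"), 0, data, data, data)
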