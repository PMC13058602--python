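"""Design-matrix assembly, composite loss, CV training and importance."""

import numpy as np
import pandas as pd
import pytest

from padbp import FEATURE_NAMES, ModelConfig, assemble_inputs, composite_loss
from padbp.bpnet import (
    PWV_COLUMN,
    Scaler,
    _loss_grad_wrt_pred,
    _mono_pairs,
    permutation_importance,
    predict,
    train_cv,
    train_model,
)


def _feature_frame(n, rng, valid=None):
    df = pd.DataFrame(
        {
            "t_start": np.arange(n) * 5.0,
            "t_end": np.arange(n) * 5.0 + 10.0,
            "mean_dc": rng.normal(0, 0.1, n),
            "ptt": rng.uniform(0.15, 0.25, n),
            "hr": rng.normal(62, 3, n),
            "lf_hrv": rng.uniform(100, 2000, n),
            "ij_interval": rng.normal(0.04, 0.002, n),
            "valid": np.ones(n, bool) if valid is None else valid,
            "ref_sbp": rng.normal(120, 8, n),
            "ref_dbp": rng.normal(80, 5, n),
        }
    )
    df["pwv"] = 1.0 / df["ptt"]
    return df


META = {"age": 40.0, "baseline_sbp": 118.0, "baseline_dbp": 79.0}


class TestAssembly:
    def test_shape_is_n_by_seven(self, rng):
        x = assemble_inputs(_feature_frame(10, rng), META, target="sbp")
        assert x.shape == (10, 7)

    def test_invalid_rows_dropped(self, rng):
        valid = np.ones(10, bool)
        valid[3] = False
        x = assemble_inputs(_feature_frame(10, rng, valid), META)
        assert x.shape[0] == 9

    def test_missing_baseline_rejected(self, rng):
        with pytest.raises(ValueError, match="calibration"):
            assemble_inputs(_feature_frame(5, rng), {"age": 40.0}, target="sbp")

    def test_scaler_standardizes_and_guards_zero_sd(self, rng):
        x = rng.normal(5.0, 2.0, size=(50, 3))
        x[:, 2] = 7.0  # constant column
        sc = Scaler.fit(x)
        xs = sc.transform(x)
        assert np.allclose(xs[:, :2].mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(xs[:, :2].std(axis=0), 1.0, atol=1e-12)
        assert sc.sd[2] == 1.0 and np.allclose(xs[:, 2], 0.0)


class TestCompositeLoss:
    def test_perfect_fit_zero_loss(self, rng):
        y = rng.normal(120, 5, 20)
        v = rng.uniform(4, 6, 20)
        assert composite_loss(y, y, v, weights=(0, 0, 0)) == 0.0

    def test_constant_offset_isolates_mse(self, rng):
        y = rng.normal(120, 5, 30)
        v = rng.uniform(4, 6, 30)
        # gradient term vanishes for a constant offset; mono hinge off
        loss = composite_loss(y + 3.0, y, v, weights=(1.0, 0.0, 0.0))
        assert loss == pytest.approx(9.0)

    def test_monotonicity_hinge_fires_on_inversion(self):
        pred = np.array([100.0, 95.0, 90.0])  # decreasing while PWV increases
        ref = pred.copy()
        pwv = np.array([4.0, 5.0, 6.0])
        loss = composite_loss(pred, ref, pwv, weights=(0.0, 1.0, 0.0))
        # hinge on all 3 pairs: 5*1 + 10*2 + 5*1 averaged
        assert loss == pytest.approx((5.0 + 20.0 + 5.0) / 3.0)
        # aligned direction: no penalty
        rising = pred[::-1]
        assert composite_loss(rising, rising, pwv, weights=(0.0, 1.0, 0.0)) == pytest.approx(0.0)

    def test_zero_weights_reduce_to_mse(self, rng):
        p = rng.normal(0, 1, 40)
        y = rng.normal(0, 1, 40)
        v = rng.uniform(4, 6, 40)
        assert composite_loss(p, y, v, weights=(0, 0, 0)) == pytest.approx(
            np.mean((p - y) ** 2)
        )

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            composite_loss(np.zeros(3), np.zeros(4), np.zeros(3))

    def test_analytic_gradient_matches_finite_differences(self, rng):
        n = 12
        pred = rng.normal(0, 1, n)
        ref = rng.normal(0, 1, n)
        pwv = rng.uniform(4, 6, n)
        subj = np.repeat([0, 1], 6)
        w = (0.7, 0.3, 0.0)
        mono = _mono_pairs(n)
        g = _loss_grad_wrt_pred(pred, ref, pwv, w, subj, mono)
        eps = 1e-6
        for k in range(n):
            pp = pred.copy()
            pp[k] += eps
            pm = pred.copy()
            pm[k] -= eps
            num = (
                composite_loss(pp, ref, pwv, w, subjects=subj)
                - composite_loss(pm, ref, pwv, w, subjects=subj)
            ) / (2 * eps)
            assert num == pytest.approx(g[k], rel=1e-4, abs=1e-8)


def _linear_dataset(n, rng, noise_sd=3.0):
    """BP = alpha*PWV + beta*mean_dc + noise — recoverable by construction."""
    x = np.zeros((n, 7))
    x[:, 0] = rng.normal(0, 0.2, n)  # mean_dc
    x[:, 1] = rng.uniform(4, 7, n)  # pwv
    x[:, 2] = rng.normal(62, 3, n)
    x[:, 3] = rng.uniform(100, 2000, n)
    x[:, 4] = rng.normal(0.04, 0.002, n)
    x[:, 5] = 40.0
    x[:, 6] = 118.0
    y = 80.0 + 8.0 * x[:, 1] + 40.0 * x[:, 0] + rng.normal(0, noise_sd, n)
    return x, y


class TestTraining:
    def test_linear_mapping_recovered_out_of_fold(self, rng):
        x, y = _linear_dataset(200, rng)
        cfg = ModelConfig(mode="intermittent", seed=0, epochs=400)
        cv = train_cv(x, y, cfg)
        r = np.corrcoef(cv.oof_pred, y)[0, 1]
        assert r >= 0.9

    def test_same_seed_identical_folds_and_predictions(self, rng):
        x, y = _linear_dataset(60, rng)
        cfg = ModelConfig(mode="intermittent", seed=3, epochs=100)
        a = train_cv(x, y, cfg)
        b = train_cv(x, y, cfg)
        assert np.array_equal(a.fold_assignments, b.fold_assignments)
        assert np.array_equal(a.oof_pred, b.oof_pred)

    def test_train_test_gap_small_on_well_specified_data(self, rng):
        x, y = _linear_dataset(600, rng)
        cfg = ModelConfig(mode="intermittent", seed=1, epochs=400)
        cv = train_cv(x, y, cfg)
        gap = abs(cv.test_rmse.mean() - cv.train_rmse.mean()) / cv.train_rmse.mean()
        assert gap < 0.10

    def test_every_window_predicted_once(self, rng):
        x, y = _linear_dataset(50, rng)
        cv = train_cv(x, y, ModelConfig(mode="intermittent", epochs=50))
        assert np.isfinite(cv.oof_pred).all()
        counts = np.bincount(cv.fold_assignments)
        assert counts.sum() == 50 and (cv.fold_assignments >= 0).all()

    def test_no_fold_leakage_in_scaler(self, rng):
        """Each fold's scaler must equal statistics of its training rows only."""
        x, y = _linear_dataset(40, rng)
        cfg = ModelConfig(mode="intermittent", seed=2, epochs=20)
        cv = train_cv(x, y, cfg)
        from sklearn.model_selection import KFold

        for f, (tr, te) in enumerate(KFold(10, shuffle=True, random_state=cfg.seed).split(x)):
            assert np.allclose(cv.models[f].scaler.mean, x[tr].mean(axis=0))

    def test_tiny_dataset_falls_back_to_loo(self, rng):
        x, y = _linear_dataset(8, rng)
        cv = train_cv(x, y, ModelConfig(mode="intermittent", epochs=20))
        assert len(np.unique(cv.fold_assignments)) == 8

    def test_mode_selects_architecture(self):
        assert ModelConfig(mode="intermittent").hidden_sizes == (16, 8, 4)
        assert ModelConfig(mode="continuous").hidden_sizes == (128, 32, 16)


class TestPredict:
    def test_mean_inputs_predict_near_target_mean(self, rng):
        x, y = _linear_dataset(200, rng)
        model = train_model(x, y, ModelConfig(mode="intermittent", epochs=300))
        at_mean = predict(model, x.mean(axis=0, keepdims=True))[0]
        assert abs(at_mean - y.mean()) < y.std()

    def test_deterministic_and_finite_at_extremes(self, rng):
        x, y = _linear_dataset(100, rng)
        model = train_model(x, y, ModelConfig(mode="intermittent", epochs=100))
        extreme = x.mean(axis=0) + 5.0 * x.std(axis=0)
        p1 = predict(model, np.vstack([extreme, -extreme]))
        p2 = predict(model, np.vstack([extreme, -extreme]))
        assert np.all(np.isfinite(p1)) and np.array_equal(p1, p2)

    def test_nan_features_rejected(self, rng):
        x, y = _linear_dataset(50, rng)
        model = train_model(x, y, ModelConfig(mode="intermittent", epochs=20))
        bad = x[:1].copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            predict(model, bad)


class TestImportance:
    def test_pwv_only_dependence_scores_pwv_top(self, rng):
        x = np.zeros((300, 7))
        for j in range(7):
            x[:, j] = rng.normal(0, 1, 300)
        y = 100.0 + 10.0 * x[:, PWV_COLUMN] + rng.normal(0, 0.5, 300)
        model = train_model(x, y, ModelConfig(mode="intermittent", epochs=400))
        scores = permutation_importance(model, x, y, seed=0)
        assert scores["pwv"] == 1.0
        others = [v for k, v in scores.items() if k != "pwv"]
        assert max(others) < 0.2

    def test_top_score_is_exactly_one(self, rng):
        x, y = _linear_dataset(100, rng)
        model = train_model(x, y, ModelConfig(mode="intermittent", epochs=100))
        scores = permutation_importance(model, x, y, seed=1)
        assert max(scores.values()) == 1.0
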