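import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kneeload.errors import InvalidArgumentError, SingularDesignError
from kneeload.gait_features import RESPONSE_VARIABLES
from kneeload.prediction_models import (
    PREDICTORS,
    AnnModel,
    MinMaxNormalizer,
    TrainingConfig,
    _residuals_and_jacobian,
    fit_mlr,
    load_models,
    save_models,
    train_all_peaks,
    train_ann,
    train_ann_with_pretraining,
)


def nrmse(pred, ref):
    return np.sqrt(np.mean((pred - ref) ** 2)) / np.mean(ref)


@pytest.fixture(scope="module")
def split_linear(linear_training_table):
    df = linear_training_table
    return df.iloc[:500].reset_index(drop=True), df.iloc[500:].reset_index(drop=True)


class TestNormalization:
    def test_endpoints_and_midpoint(self):
        norm = MinMaxNormalizer.fit(np.array([[50.0], [100.0]]))
        np.testing.assert_allclose(norm.apply(np.array([[50.0]])), [[-1.0]])
        np.testing.assert_allclose(norm.apply(np.array([[100.0]])), [[1.0]])
        np.testing.assert_allclose(norm.apply(np.array([[75.0]])), [[0.0]])

    def test_extrapolation_allowed(self):
        norm = MinMaxNormalizer.fit(np.array([[50.0], [100.0]]))
        np.testing.assert_allclose(norm.apply(np.array([[110.0]])), [[1.4]])

    def test_constant_column_maps_to_zero(self):
        with pytest.warns(UserWarning):
            norm = MinMaxNormalizer.fit(np.array([[5.0], [5.0]]))
        np.testing.assert_allclose(norm.apply(np.array([[5.0]])), [[0.0]])
        np.testing.assert_allclose(norm.invert(np.array([[0.0]])), [[5.0]])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=20, unique=True))
    def test_apply_invert_identity(self, values):
        x = np.array(values)[:, None]
        norm = MinMaxNormalizer.fit(x)
        np.testing.assert_allclose(norm.invert(norm.apply(x)), x, atol=1e-9)


class TestAnn:
    def test_constant_targets_predicted_within_one_newton(self, split_linear):
        train, test = split_linear
        df = train.copy()
        df["resp"] = 2500.0
        model = train_ann(df, "resp", "full", TrainingConfig(seed=1))
        np.testing.assert_allclose(model.predict(test), 2500.0, atol=1.0)

    def test_noiseless_linear_data_low_nrmse(self, split_linear):
        train, test = split_linear
        ann = train_ann(train, "max_summed", "full", TrainingConfig(seed=3))
        mlr = fit_mlr(train, "max_summed")
        ref = test["max_summed"].to_numpy()
        ann_nrmse = nrmse(ann.predict(test), ref)
        mlr_nrmse = nrmse(mlr.predict(test), ref)
        assert ann_nrmse <= 0.02
        assert abs(ann_nrmse - mlr_nrmse) <= 0.02

    def test_fixed_seed_bitwise_identical(self, split_linear):
        train, _ = split_linear
        a = train_ann(train, "lr_medial", "full", TrainingConfig(seed=3))
        b = train_ann(train, "lr_medial", "full", TrainingConfig(seed=3))
        assert np.array_equal(a.theta, b.theta)
        assert (a.alpha, a.beta) == (b.alpha, b.beta)

    def test_prediction_matches_formula(self, split_linear):
        """Model output equals an independent evaluation of
        invert(a*tanh(w.z + b1) + b2)."""
        train, test = split_linear
        m = train_ann(train, "te_summed", "full", TrainingConfig(seed=3))
        x = test[list(PREDICTORS)].to_numpy()
        z = m.norm_in.apply(x)
        by_hand = m.norm_out.invert(
            (m.a * np.tanh(z @ m.w + m.b1) + m.b2)[:, None]
        ).ravel()
        np.testing.assert_allclose(m.predict(test), by_hand, atol=1e-12)

    def test_monotone_response_surface(self, split_linear):
        """A single tanh unit is monotone in every input."""
        train, _ = split_linear
        m = train_ann(train, "max_summed", "full", TrainingConfig(seed=3))
        base = train[list(PREDICTORS)].median().to_numpy()
        for j in range(len(PREDICTORS)):
            grid = np.tile(base, (25, 1))
            grid[:, j] = np.linspace(base[j] * 0.5, base[j] * 1.5 + 1.0, 25)
            out = m.predict(grid)
            d = np.diff(out)
            assert np.all(d >= -1e-9) or np.all(d <= 1e-9)

    def test_zero_hidden_weights_constant_prediction(self, split_linear):
        _, test = split_linear
        m = train_ann(test.iloc[:50], "max_summed", "full", TrainingConfig(seed=0))
        m.w = np.zeros_like(m.w)
        out = m.predict(test.iloc[50:80])
        assert np.ptp(out) == 0.0

    def test_too_few_rows_rejected(self, split_linear):
        train, _ = split_linear
        with pytest.raises(InvalidArgumentError):
            train_ann(train.iloc[:5], "max_summed")

    def test_shrinkage_with_noise(self, split_linear):
        """The effective parameter count gamma drops when the targets are
        mostly noise (Bayesian regularization at work)."""
        train, _ = split_linear
        gammas = {}
        for sd, tag in ((0.0, "clean"), (4000.0, "noisy")):
            g = []
            for seed in (0, 1, 2):
                df = train.copy()
                rng = np.random.default_rng(seed)
                df["resp"] = df["max_summed"] + rng.normal(0, sd, len(df))
                g.append(train_ann(df, "resp", "full",
                                   TrainingConfig(seed=seed)).gamma)
            gammas[tag] = np.mean(g)
        assert gammas["noisy"] < gammas["clean"]

    def test_pretraining_never_hurts_final_fit(self, split_linear):
        """Fine-tuning only accepts objective-decreasing steps, so the final
        data misfit cannot exceed the pre-trained starting point's."""
        train, test = split_linear
        cfg = TrainingConfig(seed=4)
        pre_df = test.copy()
        model = train_ann_with_pretraining(pre_df, train, "max_summed",
                                           "full", cfg)
        pre_only = train_ann(pre_df, "max_summed", "full", cfg,
                             norm_in=model.norm_in, norm_out=model.norm_out)
        z = model.norm_in.apply(train[list(PREDICTORS)].to_numpy())
        t = np.asarray(
            model.norm_out.apply(train[["max_summed"]].to_numpy())
        ).ravel()
        r_final, _ = _residuals_and_jacobian(model.theta, z, t)
        r_init, _ = _residuals_and_jacobian(pre_only.theta, z, t)
        assert r_final @ r_final <= r_init @ r_init + 1e-12


class TestMlr:
    def test_single_predictor_recovery(self, split_linear):
        train, _ = split_linear
        df = train.copy()
        df["resp"] = 20.0 * df["mass"] + 100.0
        m = fit_mlr(df, "resp")
        assert m.coef[0] == pytest.approx(20.0, abs=1e-8)
        np.testing.assert_allclose(m.coef[1:], 0.0, atol=1e-8)
        assert m.intercept == pytest.approx(100.0, abs=1e-6)

    def test_matches_normal_equations(self, split_linear):
        train, _ = split_linear
        m = fit_mlr(train, "lr_lateral")
        x = train[list(PREDICTORS)].to_numpy()
        design = np.column_stack([x, np.ones(len(x))])
        beta = np.linalg.solve(design.T @ design, design.T @ train["lr_lateral"])
        np.testing.assert_allclose(
            np.concatenate([m.coef, [m.intercept]]), beta, atol=1e-8
        )

    def test_residuals_orthogonal_to_design(self, split_linear):
        train, _ = split_linear
        m = fit_mlr(train, "te_medial")
        resid = train["te_medial"].to_numpy() - m.predict(train)
        x = train[list(PREDICTORS)].to_numpy()
        np.testing.assert_allclose(x.T @ resid / len(resid), 0.0, atol=1e-6)

    def test_rank_deficient_design_rejected(self, split_linear):
        train, _ = split_linear
        df = train.copy()
        df["height"] = 2.0 * df["mass"] + 1.0  # exact collinearity
        with pytest.raises(SingularDesignError):
            fit_mlr(df, "max_summed")

    def test_inactive_predictors_zero_coefficient(self, split_linear):
        train, _ = split_linear
        m = fit_mlr(train, "max_summed", "demographic")
        assert m.coef[PREDICTORS.index("speed")] == 0.0
        assert m.coef[PREDICTORS.index("kfa")] == 0.0


class TestTrainAllPeaks:
    def test_nine_model_pairs(self, split_linear):
        train, _ = split_linear
        models = train_all_peaks(train, cfg=TrainingConfig(seed=2, max_epochs=60))
        assert set(models) == set(RESPONSE_VARIABLES)
        assert len(models) == 9

    def test_training_beats_intercept_only(self, split_linear):
        train, _ = split_linear
        models = train_all_peaks(train, cfg=TrainingConfig(seed=2, max_epochs=60))
        for resp, (ann, _) in models.items():
            ref = train[resp].to_numpy()
            model_rmse = np.sqrt(np.mean((ann.predict(train) - ref) ** 2))
            intercept_rmse = np.std(ref)
            assert model_rmse <= intercept_rmse

    def test_serialization_round_trip(self, split_linear, tmp_path):
        train, test = split_linear
        models = train_all_peaks(train.iloc[:60],
                                 cfg=TrainingConfig(seed=2, max_epochs=30))
        path = tmp_path / "models.json"
        save_models(models, path)
        loaded = load_models(path)
        for resp in RESPONSE_VARIABLES:
            np.testing.assert_array_equal(
                models[resp][0].predict(test), loaded[resp][0].predict(test)
            )
            np.testing.assert_array_equal(
                models[resp][1].predict(test), loaded[resp][1].predict(test)
            )
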