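"""Calibration fitting, evaluation arithmetic, and regression properties."""

import numpy as np
import pandas as pd
import pytest

import fermsense as fs
from fermsense.calibration import predict_od

from conftest import forward_feature_table

FEATS = list(fs.FEATURE_NAMES)


def random_dataset(n, seed, sigma=0.0, coefs=(3.0, 1.2, 0.7, 0.2), intercept=20.0):
    """Random feature table with a known (non-negative) linear truth."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.5, 2.0, size=(n, 4)) * np.array([1.0, 50.0, 0.5, 5.0])
    y = X @ np.asarray(coefs) + intercept + sigma * rng.standard_normal(n)
    assert (y >= 0).all()
    df = pd.DataFrame(X, columns=FEATS)
    df["offline_od"] = y
    return df


def zscore_train(df, train_frac=0.8, seed=0):
    """Independent standardization + split mirroring the fit contract."""
    train, test = fs.split_train_test(df, train_frac, seed)
    X = train[FEATS].to_numpy()
    mu, sd = X.mean(0), X.std(0, ddof=1)
    return train, test, (X - mu) / sd, train["offline_od"].to_numpy()


class TestOLSR:
    def test_exact_linear_truth_recovered(self):
        df = random_dataset(60, seed=1, sigma=0.0)
        res = fs.InlineODModel(df).fit(method="olsr", seed=1)
        pred = res.predict(df)
        rmse = np.sqrt(np.mean((pred - df["offline_od"]) ** 2))
        assert rmse < 1e-8
        assert res.metrics_test.r2 > 1 - 1e-12

    def test_matches_normal_equation_oracle(self):
        df = random_dataset(20, seed=7, sigma=2.0)
        res = fs.InlineODModel(df).fit(method="olsr", seed=3)
        _, _, Z, y = zscore_train(df, seed=3)
        beta = np.linalg.solve(Z.T @ Z, Z.T @ (y - y.mean()))
        assert np.allclose(res.spec.coefficients, beta, atol=1e-10)
        assert res.intercept == pytest.approx(y.mean())

    def test_matches_sklearn(self):
        sklearn_lm = pytest.importorskip("sklearn.linear_model")
        df = random_dataset(40, seed=9, sigma=1.0)
        res = fs.InlineODModel(df).fit(method="olsr", seed=2)
        _, _, Z, y = zscore_train(df, seed=2)
        ref = sklearn_lm.LinearRegression().fit(Z, y)
        assert np.allclose(res.spec.coefficients, ref.coef_, atol=1e-9)
        assert res.intercept == pytest.approx(ref.intercept_, abs=1e-9)

    def test_residuals_orthogonal_to_features(self, olsr_seed1, corpus_seed1):
        corpus, _ = corpus_seed1
        spec = olsr_seed1.spec
        train = corpus.iloc[olsr_seed1.train_index]
        Z = (train[FEATS].to_numpy() - spec.feature_means) / spec.feature_sds
        resid = Z @ spec.coefficients + spec.intercept \
            - train["offline_od"].to_numpy()
        # normalize: orthogonality per unit column / residual norm
        dots = np.abs(Z.T @ resid) / (np.linalg.norm(Z, axis=0)
                                      * np.linalg.norm(resid))
        assert np.all(dots < 1e-8)

    def test_singular_design_names_collinear_features(self):
        df = random_dataset(30, seed=4)
        df["refl_ma"] = 2.0 * df["inv_trans_ma"]  # exact collinearity
        with pytest.raises(fs.SingularDesignError) as e:
            fs.InlineODModel(df).fit(method="olsr", seed=0)
        assert {"inv_trans_ma", "refl_ma"} & set(e.value.collinear_features)

    def test_zero_variance_feature_rejected(self):
        df = random_dataset(30, seed=4)
        df["antifoam_pct"] = 0.0
        with pytest.raises(fs.SingularDesignError) as e:
            fs.InlineODModel(df).fit(method="olsr", seed=0)
        assert "antifoam_pct" in e.value.collinear_features

    def test_noiseless_plateau_parameter_recovery(self, plateau_table, exact_model):
        # the forward model is exactly linear in the identifiable features,
        # so a noiseless fit over OD 0..140 reproduces truth to machine
        # precision ...
        pred = exact_model.predict(plateau_table)
        rmse = float(np.sqrt(np.mean((pred - plateau_table["offline_od"]) ** 2)))
        assert rmse < 1e-6
        # ... while the full four-term set is exactly collinear on plateau
        # data (all terms affine/quadratic in the two factors OD and AF%),
        # which the rank check must report rather than silently solve
        with pytest.raises(fs.SingularDesignError):
            fs.InlineODModel(plateau_table).fit(method="olsr", seed=0)


class TestRidge:
    def test_lambda_zero_equals_olsr(self):
        df = random_dataset(30, seed=5, sigma=1.0)
        a = fs.InlineODModel(df).fit(method="olsr", seed=1)
        b = fs.InlineODModel(df).fit(method="ridge", ridge_lambda=0.0, seed=1)
        assert np.allclose(a.spec.coefficients, b.spec.coefficients, atol=1e-10)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-12)

    def test_huge_lambda_shrinks_to_training_mean(self):
        df = random_dataset(30, seed=6, sigma=1.0)
        res = fs.InlineODModel(df).fit(method="ridge", ridge_lambda=1e12, seed=1)
        assert np.all(np.abs(res.spec.coefficients) < 1e-6)
        train, _ = fs.split_train_test(df, 0.8, 1)
        pred = res.predict(df)
        assert np.allclose(pred, train["offline_od"].mean(), atol=1e-4)

    def test_matches_closed_form_oracle_and_sklearn(self):
        df = random_dataset(30, seed=8, sigma=2.0)
        lam = 1.0
        res = fs.InlineODModel(df).fit(method="ridge", ridge_lambda=lam, seed=2)
        _, _, Z, y = zscore_train(df, seed=2)
        beta = np.linalg.solve(Z.T @ Z + lam * np.eye(4), Z.T @ (y - y.mean()))
        assert np.allclose(res.spec.coefficients, beta, atol=1e-10)
        sklearn_lm = pytest.importorskip("sklearn.linear_model")
        ref = sklearn_lm.Ridge(alpha=lam).fit(Z, y)
        assert np.allclose(res.spec.coefficients, ref.coef_, atol=1e-8)

    def test_monotone_shrinkage(self):
        df = random_dataset(40, seed=10, sigma=2.0)
        model = fs.InlineODModel(df)
        norms = [
            np.linalg.norm(model.fit(method="ridge", ridge_lambda=lam,
                                     seed=1).spec.coefficients)
            for lam in (0.0, 0.1, 1.0, 10.0, 100.0, 1e4)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))

    def test_negative_lambda_rejected(self):
        df = random_dataset(20, seed=1)
        with pytest.raises(fs.InvalidInputError):
            fs.InlineODModel(df).fit(method="ridge", ridge_lambda=-1.0)


class TestPredict:
    def test_zero_model_predicts_zero(self):
        spec = fs.ODModelSpec(FEATS, np.zeros(4), 0.0, 0.0,
                              np.zeros(4), np.ones(4))
        assert predict_od(spec, dict(zip(FEATS, [1.0, 2.0, 0.5, 2.0]))) == 0.0

    def test_negative_linear_output_clamped(self):
        spec = fs.ODModelSpec(FEATS, np.zeros(4), -1.2, 0.0,
                              np.zeros(4), np.ones(4))
        assert predict_od(spec, dict(zip(FEATS, [0, 0, 0, 0]))) == 0.0

    def test_feature_name_mismatch_raises(self, exact_model):
        with pytest.raises(fs.SchemaError):
            exact_model.predict({"inv_trans_ma": 0.01})

    def test_monotone_in_inverse_transmission(self, exact_model):
        # with a positive inv_trans coefficient and other terms fixed,
        # predictions never decrease as inverse transmission rises
        spec = exact_model.spec
        assert spec.coefficients[0] > 0
        grid = np.linspace(0.01, 0.8, 50)
        preds = [predict_od(spec, dict(zip(FEATS, [g, 50.0, 0.2, g * 50.0 * 0])))
                 for g in grid]
        assert np.all(np.diff(preds) >= 0)


class TestSplit:
    def test_sizes_match_floor_rule(self, corpus_seed1):
        corpus, _ = corpus_seed1
        train, test = fs.split_train_test(corpus, 0.8, seed=0)
        assert (len(train), len(test)) == (127, 32)

    def test_reproducible_and_partition(self):
        df = random_dataset(37, seed=3)
        a1, b1 = fs.split_train_test(df, 0.8, seed=42)
        a2, b2 = fs.split_train_test(df, 0.8, seed=42)
        assert a1.index.equals(a2.index) and b1.index.equals(b2.index)
        merged = sorted([*a1.index, *b1.index])
        assert merged == list(range(37))

    def test_too_few_samples(self):
        with pytest.raises(fs.InvalidInputError):
            fs.split_train_test(random_dataset(4, seed=0), 0.8, 0)


class TestMetrics:
    def test_perfect_prediction(self):
        m = fs.regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.rmse == 0.0 and m.r2 == 1.0

    def test_hand_arithmetic(self):
        m = fs.regression_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert m.rmse == pytest.approx(np.sqrt(2.0 / 3.0))
        assert m.r2 == pytest.approx(0.0)
        assert m.residual_mean == pytest.approx(0.0)
        assert m.residual_sd == pytest.approx(1.0)

    def test_translation_shifts_mean_not_sd(self):
        rng = np.random.default_rng(0)
        obs = rng.uniform(0, 100, 25)
        pred = obs + rng.normal(0, 3, 25)
        m0 = fs.regression_metrics(pred, obs)
        m1 = fs.regression_metrics(pred + 2.5, obs)
        assert m1.residual_mean == pytest.approx(m0.residual_mean + 2.5)
        assert m1.residual_sd == pytest.approx(m0.residual_sd)

    def test_zero_variance_observed_rejected(self):
        with pytest.raises(fs.InvalidInputError):
            fs.regression_metrics([1.0, 2.0], [5.0, 5.0])


class TestImportance:
    def test_single_feature(self):
        spec = fs.ODModelSpec(("a",), [2.0], 0.0, 0.0, [0.0], [1.0])
        assert fs.feature_importance(spec) == {"a": 1.0}

    def test_equal_coefficients_split_evenly(self):
        imp = fs.feature_importance(np.array([1.5, -1.5]), ["a", "b"])
        assert imp == {"a": 0.5, "b": 0.5}

    def test_inverse_transmission_ranks_first_on_corpus(self, olsr_seed1):
        imp = olsr_seed1.importance
        assert max(imp, key=imp.get) == "inv_trans_ma"


class TestIntervalArithmetic:
    def test_expected_inline_band(self):
        lo, hi = fs.prediction_interval(80.8, 1.74, 6.56)
        assert hi == pytest.approx(89.10)
        assert lo == pytest.approx(75.98)

    def test_degenerate_band(self):
        assert fs.prediction_interval(42.0, 0.0, 0.0) == (42.0, 42.0)

    def test_widths(self):
        assert fs.interval_width(77.4, 84.2) == pytest.approx(6.8)
        assert fs.interval_width(75.9, 89.1) == pytest.approx(13.2)
        assert fs.interval_width(3.0, 3.0) == 0.0
        with pytest.raises(fs.InvalidInputError):
            fs.interval_width(2.0, 1.0)


class TestPercentDeviation:
    def test_identical_measurements(self):
        assert fs.percent_deviation([80.0] * 9) == 0.0

    def test_two_point_hand_arithmetic(self):
        assert fs.percent_deviation([79.0, 81.0]) == pytest.approx(
            100.0 * np.sqrt(2.0) / 80.0)

    def test_operator_table_stochastic_scale(self):
        # 3 operators x 9 readings around OD 80.8 with SD ~3.47 should give
        # a pooled CV near 4.3% (Monte-Carlo error ~0.6 at n=27)
        rng = np.random.default_rng(42)
        tab = pd.DataFrame({
            "operator_id": np.repeat(["A", "B", "C"], 9),
            "sample_id": np.tile(np.arange(9), 3),
            "od600": 80.8 + 3.47 * rng.standard_normal(27),
        })
        assert fs.percent_deviation(tab) == pytest.approx(4.3, abs=1.3)

    def test_invalid_inputs(self):
        with pytest.raises(fs.InvalidInputError):
            fs.percent_deviation([80.0])
        with pytest.raises(fs.InvalidInputError):
            fs.percent_deviation([1.0, -1.0])


def test_summary_reports_fit(olsr_seed1):
    text = olsr_seed1.summary()
    assert "OLSR" in text and "inv_trans_ma" in text
    assert f"{olsr_seed1.metrics_test.rmse:.3f}" in text


def test_exact_model_recovers_forward_model(exact_model, default_probe):
    # cross-check on fresh plateau points not in the fitting grid
    fresh = forward_feature_table(default_probe, od=[5.0, 77.7, 133.0],
                                  af_pct=[0.1, 0.4, 0.25])
    pred = exact_model.predict(fresh)
    assert np.allclose(pred, fresh["offline_od"], atol=1e-7)
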