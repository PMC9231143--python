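import math

import numpy as np
import pandas as pd
import pytest

from mmgforce import (
    DataError,
    ForceSVR,
    ICSParams,
    Metrics,
    NumericalError,
    SVRConfig,
    compute_metrics,
    evaluate_protocol,
    svr_fitness,
    tune_svr,
)
from mmgforce.features import FeatureMatrix
from mmgforce.model import SVR_BOUNDS

TINY_ICS = dict(n_nests=6, T=8)


def linear_dataset(n=120, p=4, noise=0.05, seed=0):
    """Learnable regression data: target is a linear map of the features."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = 50.0 + 10.0 * X[:, 0] + 3.0 * X[:, 1] + noise * rng.normal(size=n)
    return X, y


class TestMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.rmse == 0.0 and m.mape == 0.0 and m.r == pytest.approx(1.0)

    def test_hand_worked_example(self):
        m = compute_metrics([1.0, 2.0], [2.0, 4.0])
        assert m.rmse == pytest.approx(math.sqrt(0.5 * (1 + 4)), rel=1e-12)
        assert m.mape == pytest.approx(1.0, rel=1e-12)

    def test_affine_prediction_has_unit_correlation(self, rng):
        y = rng.normal(50.0, 10.0, 40)
        m = compute_metrics(y, 2.0 * y + 5.0)
        assert m.r == pytest.approx(1.0)

    def test_zero_targets_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero target"):
            m = compute_metrics([0.0, 1.0, 2.0], [0.5, 1.0, 2.0])
        assert m.mape == 0.0

    def test_constant_sequence_rejected(self):
        with pytest.raises(NumericalError):
            compute_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_zero_error_iff_zero_mape(self, rng):
        y = rng.uniform(10.0, 100.0, 30)
        yp = y + rng.normal(0, 1.0, 30)
        m = compute_metrics(y, yp)
        assert (m.rmse == 0.0) == (m.mape == 0.0) == bool(np.all(y == yp))


class TestSVRConfig:
    def test_gamma_convention(self):
        cfg = SVRConfig(C=1.0, sigma=2.0)
        assert cfg.gamma == pytest.approx(1.0 / 8.0)
        est = cfg.make_estimator()
        assert est.gamma == cfg.gamma and est.C == 1.0

    def test_rbf_kernel_value_matches_width_parameterisation(self, rng):
        """k(u, w) = exp(-||u-w||^2 / (2 sigma^2)) under the configured gamma."""
        from sklearn.metrics.pairwise import rbf_kernel

        sigma = 3.0
        cfg = SVRConfig(C=1.0, sigma=sigma)
        u = rng.normal(size=(1, 4))
        w = rng.normal(size=(1, 4))
        expected = np.exp(-np.sum((u - w) ** 2) / (2 * sigma**2))
        assert rbf_kernel(u, w, gamma=cfg.gamma)[0, 0] == pytest.approx(expected)


class TestFitness:
    def test_deterministic(self):
        X, y = linear_dataset()
        a = svr_fitness((10.0, 1.0), X, y, seed=3)
        b = svr_fitness((10.0, 1.0), X, y, seed=3)
        assert a == b

    def test_nonnegative(self):
        X, y = linear_dataset()
        assert svr_fitness((1.0, 1.0), X, y) >= 0.0

    def test_sensible_parameters_beat_degenerate(self):
        """(C=100, sigma=5) must beat the underfitting corner
        (C=0.001, sigma=500) on linear data in nearly every seed."""
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 2))
            y = X[:, 0] + 0.01 * rng.normal(size=60)
            good = svr_fitness((100.0, 5.0), X, y, seed=seed)
            bad = svr_fitness((0.001, 500.0), X, y, seed=seed)
            wins += good < bad
        assert wins >= 95

    def test_too_few_rows_rejected(self):
        with pytest.raises(DataError):
            svr_fitness((1.0, 1.0), np.zeros((10, 2)), np.zeros(10))


class TestTuneSVR:
    def test_result_within_bounds_and_deterministic(self):
        X, y = linear_dataset()
        params = ICSParams(bounds=SVR_BOUNDS, seed=5, **TINY_ICS)
        cfg1, trace1 = tune_svr(X, y, params=params, seed=5)
        cfg2, trace2 = tune_svr(X, y, params=params, seed=5)
        assert 0.001 <= cfg1.C <= 500.0 and 0.001 <= cfg1.sigma <= 500.0
        assert (cfg1.C, cfg1.sigma) == (cfg2.C, cfg2.sigma)
        np.testing.assert_array_equal(
            trace1.best_fitness_history, trace2.best_fitness_history
        )

    def test_beats_random_search_on_its_objective(self):
        X, y = linear_dataset()
        for seed in (0, 1, 2):
            cfg, trace = tune_svr(X, y, seed=seed)  # default search budget
            rng = np.random.default_rng(100 + seed)
            draws = rng.uniform(0.001, 500.0, size=(20, 2))
            random_losses = [
                svr_fitness(pos, X, y, seed=seed) for pos in draws
            ]
            assert trace.best_fitness <= min(random_losses)

    def test_never_degrades_own_objective(self):
        X, y = linear_dataset()
        params = ICSParams(bounds=SVR_BOUNDS, seed=9, **TINY_ICS)
        _, trace = tune_svr(X, y, params=params, seed=9)
        hist = trace.best_fitness_history
        assert trace.best_fitness <= hist[0]


class TestForceSVR:
    def test_interpolation_regime(self):
        X = np.tile(np.arange(5.0)[:, None], (1, 2))
        y = np.arange(5.0) * 10 + 30
        model = ForceSVR(np.tile(y, 4), np.tile(X, (4, 1)))
        res = model.fit(config=SVRConfig(C=100.0, sigma=1.0, epsilon=0.001))
        pred = res.predict(X)
        np.testing.assert_allclose(pred, y, atol=1.0)

    def test_prediction_deterministic(self):
        X, y = linear_dataset()
        res = ForceSVR(y, X).fit(config=SVRConfig(C=10.0, sigma=2.0))
        np.testing.assert_array_equal(res.predict(X), res.predict(X))

    def test_linear_data_high_correlation(self):
        X, y = linear_dataset(n=200)
        res = ForceSVR(y[:160], X[:160]).fit(
            config=SVRConfig(C=100.0, sigma=3.0)
        )
        m = res.metrics_on(X[160:], y[160:])
        assert m.r > 0.95

    def test_column_schema_enforced(self):
        X, y = linear_dataset()
        df = pd.DataFrame(X, columns=[f"c{i}" for i in range(X.shape[1])])
        res = ForceSVR(y, df).fit(config=SVRConfig(C=10.0, sigma=2.0))
        with pytest.raises(DataError, match="missing feature columns"):
            res.predict(df.rename(columns={"c0": "other"}))
        with pytest.raises(DataError):
            res.predict(X[:, :2])

    def test_summary_mentions_parameters(self):
        X, y = linear_dataset()
        res = ForceSVR(y, X).fit(config=SVRConfig(C=10.0, sigma=2.0))
        text = res.summary()
        assert "penalty C" in text and "sigma" in text

    def test_plot_estimates_smoke(self):
        X, y = linear_dataset()
        res = ForceSVR(y, X).fit(config=SVRConfig(C=10.0, sigma=2.0))
        ax = res.plot_estimates()
        assert ax.get_ylabel() == "force (N)"


def feature_matrix_with_noise(n=100, informative=3, noise=3, seed=0):
    rng = np.random.default_rng(seed)
    force = rng.uniform(30.0, 240.0, n)
    cols = {}
    for i in range(informative):
        cols[f"good{i}"] = force * rng.uniform(0.8, 1.2) + rng.normal(
            0, 2.0, n
        )
    for i in range(noise):
        cols[f"noise{i}"] = rng.normal(size=n)
    return FeatureMatrix(features=pd.DataFrame(cols), force=force)


class TestEvaluateProtocol:
    def test_split_arithmetic(self):
        fm = feature_matrix_with_noise(n=400)
        params = ICSParams(bounds=SVR_BOUNDS, **TINY_ICS)
        report = evaluate_protocol(fm, tune_params=params, n_reps=2, seed=0)
        assert report.n_train == 360 and report.n_test == 40

    def test_report_reproducible(self):
        fm = feature_matrix_with_noise()
        params = ICSParams(bounds=SVR_BOUNDS, **TINY_ICS)
        a = evaluate_protocol(fm, tune_params=params, n_reps=2, seed=4)
        b = evaluate_protocol(fm, tune_params=params, n_reps=2, seed=4)
        pd.testing.assert_frame_equal(a.per_repetition, b.per_repetition)
        assert a.seeds == b.seeds

    def test_too_small_dataset_rejected(self):
        fm = feature_matrix_with_noise(n=30)
        with pytest.raises(DataError):
            evaluate_protocol(fm, n_reps=1)

    def test_gra_selection_not_worse_than_all_features(self):
        """Dropping pure-noise columns by GRA must not hurt the mean RMSE
        over paired repetitions."""
        from mmgforce import feature_force_gra, select_combination

        fm = feature_matrix_with_noise(n=100, informative=6, noise=6, seed=2)
        res = feature_force_gra(fm)
        combo = select_combination(res, "D")
        assert all(name.startswith("good") for name in combo.names)
        params = ICSParams(bounds=SVR_BOUNDS, **TINY_ICS)
        selected = evaluate_protocol(
            fm, combination=combo, tune_params=params, n_reps=10, seed=0
        )
        everything = evaluate_protocol(
            fm, tune_params=params, n_reps=10, seed=0
        )
        assert selected.mean["rmse"] <= everything.mean["rmse"]

    def test_summary_shape(self):
        fm = feature_matrix_with_noise()
        params = ICSParams(bounds=SVR_BOUNDS, **TINY_ICS)
        report = evaluate_protocol(fm, tune_params=params, n_reps=2, seed=1)
        assert "RMSE" in report.summary()
        d = report.to_dict()
        assert set(d["mean"]) == {"rmse", "mape", "r"}
        assert len(d["repetitions"]) == 2
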