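"""Cross-validation machinery: folds, metrics, leakage, determinism."""
import numpy as np
import pandas as pd
import pytest

from texlai.errors import DomainError, TexlaiError
from texlai.modeling import (FAMILIES, ModelSpec, fit_predict, metrics,
                             run_experiment, standardize_features,
                             tenfold_split, unstandardize)


class TestTenfoldSplit:
    def test_700_samples_split_630_70(self):
        folds = tenfold_split(700, seed=1)
        for f in range(10):
            assert (folds == f).sum() == 70
            assert (folds != f).sum() == 630

    def test_partition_property(self):
        folds = tenfold_split(57, seed=2)
        assert folds.shape == (57,)
        sizes = np.bincount(folds, minlength=10)
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 57

    def test_minimum_n(self):
        folds = tenfold_split(10, seed=3)
        assert np.bincount(folds).tolist() == [1] * 10
        with pytest.raises(ValueError):
            tenfold_split(9, seed=3)

    def test_deterministic(self):
        np.testing.assert_array_equal(
            tenfold_split(100, seed=4), tenfold_split(100, seed=4)
        )


class TestMetrics:
    def test_perfect_fit(self):
        y = np.array([1.0, 2, 3, 4])
        r2, rmse, rpd = metrics(y, y)
        assert r2 == 1.0 and rmse == 0.0 and np.isinf(rpd)

    def test_mean_predictor_identity(self):
        y = np.array([1.0, 2, 3, 4, 7])
        r2, rmse, rpd = metrics(y, np.full(5, y.mean()))
        assert r2 == pytest.approx(0.0)
        assert rpd == pytest.approx(1.0)  # population-sd convention

    def test_hand_computed_example(self):
        y = np.array([1.0, 2, 3, 4])
        yhat = np.array([1.1, 1.9, 3.2, 3.8])
        r2, rmse, rpd = metrics(y, yhat)
        assert rmse == pytest.approx(np.sqrt(0.1 / 4))
        assert rpd == pytest.approx(np.sqrt(1.25) / np.sqrt(0.025))
        assert rpd == pytest.approx(y.std() / rmse)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        yhat = y + rng.normal(0, 0.1, 30)
        perm = rng.permutation(30)
        assert metrics(y, yhat) == pytest.approx(metrics(y[perm], yhat[perm]))

    def test_zero_variance_rejected(self):
        with pytest.raises(DomainError):
            metrics(np.ones(5), np.arange(5.0))


class TestStandardize:
    def test_self_application_zero_mean_unit_sd(self):
        rng = np.random.default_rng(1)
        X = rng.normal(3, 2, (40, 3))
        Xt, Xa, _ = standardize_features(X, X)
        np.testing.assert_allclose(Xt.mean(0), 0, atol=1e-12)
        np.testing.assert_allclose(Xt.std(0), 1, atol=1e-12)
        np.testing.assert_array_equal(Xt, Xa)

    def test_apply_set_keeps_training_parameters(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (40, 2))
        shifted = X + 5.0
        _, Xa, _ = standardize_features(X, shifted)
        assert np.all(Xa.mean(0) > 4)  # no re-centering on the apply set

    def test_round_trip(self):
        rng = np.random.default_rng(3)
        X = rng.normal(2, 3, (20, 4))
        Xt, _, params = standardize_features(X, X)
        np.testing.assert_allclose(unstandardize(Xt, params), X, atol=1e-12)

    def test_zero_variance_column_named(self):
        X = np.ones((10, 2))
        X[:, 1] = np.arange(10)
        with pytest.raises(DomainError, match="0"):
            standardize_features(X, X)


class TestFitPredict:
    def _linear_data(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({"f": rng.uniform(0, 1, n)})
        y = 1.0 + 3.0 * X["f"].to_numpy()
        return X, y

    def test_plsr_recovers_linear_signal(self):
        X, y = self._linear_data()
        folds = tenfold_split(len(y), seed=5)
        res = fit_predict(ModelSpec("PLSR"), X, y, folds)
        assert res.summary["val_R2"] > 0.999
        assert res.summary["val_RMSE"] < 0.01

    def test_fold_structure(self):
        X, y = self._linear_data()
        folds = tenfold_split(len(y), seed=5)
        res = fit_predict(ModelSpec("SVM"), X, y, folds)
        assert len(res.folds) == 10
        assert np.isfinite(res.oof_prediction).all()

    def test_deterministic_rerun(self):
        X, y = self._linear_data()
        rng = np.random.default_rng(1)
        y = y + rng.normal(0, 0.2, len(y))
        folds = tenfold_split(len(y), seed=5)
        a = fit_predict(ModelSpec("RF", seed=9), X, y, folds)
        b = fit_predict(ModelSpec("RF", seed=9), X, y, folds)
        assert a.summary == b.summary
        np.testing.assert_array_equal(a.oof_prediction, b.oof_prediction)

    def test_incomplete_rows_dropped(self):
        X, y = self._linear_data(60)
        X.loc[3, "f"] = np.nan
        folds = tenfold_split(len(y), seed=6)
        res = fit_predict(ModelSpec("PLSR"), X, y, folds)
        assert res.n_dropped == 1
        assert len(res.y) == 59

    def test_rf_bpnn_require_seed(self):
        with pytest.raises(ValueError):
            ModelSpec("RF")
        with pytest.raises(ValueError):
            ModelSpec("BPNN")

    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("SVM", {"kernel": "poly"})


class TestRunExperiment:
    def _table(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        t = pd.DataFrame({"lai": rng.uniform(1, 5, n)})
        t["v1"] = t["lai"] + rng.normal(0, 0.3, n)
        t["v2"] = 0.5 * t["lai"] + rng.normal(0, 0.3, n)
        t["t1"] = 2 - 0.3 * t["lai"] + rng.normal(0, 0.2, n)
        return t

    def test_counting_and_shape(self):
        t = self._table()
        sets = {"VIs": ["v1", "v2"], "TIs": ["t1"], "VIs+TIs": ["v1", "v2", "t1"]}
        out = run_experiment(t, sets, seed=3, families=("SVM", "PLSR"))
        assert len(out["results"]) == 2 * 3 * 2  # families x sets x Cal/Val
        assert set(out["results"].columns) == {
            "family", "input_set", "split", "R2", "RMSE", "RPD"
        }

    def test_empty_feature_set_refused(self):
        t = self._table()
        with pytest.raises(TexlaiError, match="empty"):
            run_experiment(t, {"VIs": []}, seed=3)

    def test_identical_seed_identical_results(self):
        t = self._table()
        sets = {"VIs": ["v1", "v2"]}
        a = run_experiment(t, sets, seed=4, families=("RF",))
        b = run_experiment(t, sets, seed=4, families=("RF",))
        pd.testing.assert_frame_equal(a["results"], b["results"])

    def test_all_families_run_and_fit_signal(self):
        t = self._table(n=150, seed=2)
        out = run_experiment(t, {"all": ["v1", "v2", "t1"]}, seed=5)
        val = out["results"].query("split == 'Val'")
        assert set(val["family"]) == set(FAMILIES)
        assert (val["R2"] > 0.5).all()


class TestNoiseFreeRecovery:
    """Without sensor noise the features determine LAI, and every family
    should recover it almost perfectly under cross-validation.

    Run at the campaign's 700-sample size (smaller plots keep extraction
    quick); the fixed SVM hyperparameters and forest granularity need a
    few hundred training samples to express the deterministic signal.
    """

    def test_all_families_exceed_r2_095_at_zero_noise(self, tmp_path):
        import pandas as pd

        from texlai.pipeline import build_feature_table
        from texlai.raster import load_rois
        from texlai.spectral import VI_NAMES
        from texlai.synthetic import CanopyParams, generate_dataset
        from texlai.texture import GLCMConfig

        params = CanopyParams(
            n_plots=140, n_dates=5, plot_size=(32, 32), noise_sd=0.0, seed=17
        )
        sim = generate_dataset(params, tmp_path / "c")
        table = build_feature_table(
            sim["rasters"], load_rois(sim["rois"]),
            pd.read_csv(sim["lai_table"]), GLCMConfig(),
        )
        out = run_experiment(table, {"VIs": list(VI_NAMES)}, seed=1)
        val = out["results"].query("split == 'Val'").set_index("family")
        for f in FAMILIES:
            assert val.loc[f, "R2"] > 0.95, (f, val.loc[f, "R2"])
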