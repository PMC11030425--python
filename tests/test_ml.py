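"""Feature imputation, splitting, and the gradient-boosted V^G model."""

import numpy as np
import pandas as pd
import pytest

from vgrecal import (
    DEFAULT_GBT_PARAMS,
    KNNFeatureImputer,
    SimulationConfig,
    ValidationError,
    VGRegressor,
    build_vg_table,
    evaluate_model,
    knn_impute,
    simulate_feature_matrix,
    split_train_test,
    train_tissue_models,
)
from vgrecal.simulate import FEATURE_NAMES, SIGNAL_FEATURES
from vgrecal.vg import MEAN_TISSUE


def feature_frame(rows, columns=None):
    columns = columns or [f"f{i}" for i in range(len(rows[0]))]
    return pd.DataFrame(rows, columns=columns,
                        index=[f"G{i}" for i in range(len(rows))], dtype=float)


class TestKNNImputer:
    def test_complete_matrix_unchanged(self, rng):
        X = feature_frame(rng.normal(size=(20, 6)).tolist())
        out = knn_impute(X, k=3)
        pd.testing.assert_frame_equal(out, X)

    def test_drop_rule_is_exactly_max_missing(self, rng):
        X = feature_frame(rng.normal(size=(30, 14)).tolist())
        X.iloc[0, :5] = np.nan   # 5 missing -> kept
        X.iloc[1, :6] = np.nan   # 6 missing -> dropped
        out = knn_impute(X, k=3, max_missing=5)
        assert "G0" in out.index and "G1" not in out.index
        assert len(out) == 29

    def test_observed_cells_untouched(self, rng):
        X = feature_frame(rng.normal(size=(40, 8)).tolist())
        holes = rng.random(X.shape) < 0.1
        Xm = X.mask(holes)
        out = knn_impute(Xm, k=4)
        observed = ~holes[: len(out)]
        for j, col in enumerate(X.columns):
            keep = out.index
            orig = Xm.loc[keep, col]
            assert np.allclose(out.loc[orig.notna().index[orig.notna()], col],
                               orig.dropna())
        assert out.notna().all().all()

    def test_duplicate_neighbors_force_exact_mean(self):
        # five identical donors with value 0.7 in the hole's column are the
        # nearest neighbours -> imputed value is exactly their mean
        donor = [1.0, 2.0, 0.7]
        rows = [donor[:] for _ in range(5)]
        rows.append([1.0, 2.0, np.nan])       # target: identical on observed cols
        rows.append([50.0, -40.0, 9.9])       # far-away distractor
        X = feature_frame(rows)
        out = knn_impute(X, k=5, max_missing=1)
        assert out.loc["G5", "f2"] == pytest.approx(0.7, abs=1e-12)

    def test_insufficient_donors_rejected(self):
        X = feature_frame([[1.0, np.nan], [2.0, np.nan], [3.0, 0.5]])
        with pytest.raises(ValidationError):
            knn_impute(X, k=2)

    def test_schema_mismatch_rejected(self, rng):
        X = feature_frame(rng.normal(size=(15, 4)).tolist())
        imp = KNNFeatureImputer(k=2).fit(X)
        with pytest.raises(ValidationError):
            imp.transform(X.rename(columns={"f0": "other"}))


class TestSplit:
    def test_eighty_twenty(self):
        ids = [f"G{i}" for i in range(100)]
        train, test = split_train_test(ids, 0.8, seed=0)
        assert len(train) == 80 and len(test) == 20
        assert set(train) | set(test) == set(ids)
        assert set(train).isdisjoint(test)

    def test_all_train_when_frac_one(self):
        ids = [f"G{i}" for i in range(20)]
        train, test = split_train_test(ids, 1.0, seed=0)
        assert len(train) == 20 and test == []

    def test_deterministic_and_order_independent(self, rng):
        ids = [f"G{i}" for i in range(57)]
        a = split_train_test(ids, 0.8, seed=9)
        b = split_train_test(list(reversed(ids)), 0.8, seed=9)
        assert a == b


class TestVGRegressor:
    def test_default_params_are_the_shipped_hyperparameters(self):
        params = VGRegressor().get_params()
        for key, value in DEFAULT_GBT_PARAMS.items():
            assert params[key] == value

    def test_constant_label_predicts_constant(self, rng):
        X = pd.DataFrame(rng.normal(size=(300, 14)), columns=FEATURE_NAMES)
        y = np.full(300, np.log(0.02))
        model = VGRegressor(random_state=0).fit(X, y)
        assert np.allclose(model.predict(X), np.log(0.02), atol=1e-6)
        vg = model.predict_vg(X)
        assert np.allclose(vg, 0.02, rtol=1e-5)
        assert (vg > 0).all()

    def test_predictions_strictly_positive(self, rng):
        X = pd.DataFrame(rng.normal(size=(300, 14)), columns=FEATURE_NAMES)
        y = rng.normal(-4, 1, size=300)
        model = VGRegressor(random_state=0).fit(X, y)
        assert (model.predict_vg(X) > 0).all()

    def test_noiseless_design_concentrates_importance(self):
        cfg = SimulationConfig(seed=4, feature_noise_sd=0.0,
                               feature_missing_rate=0.0, row_blackout_frac=0.0,
                               n_feature_genes=4000)
        X, y = simulate_feature_matrix(cfg)
        model = VGRegressor(random_state=4).fit(X, y.to_numpy())
        imp = pd.Series(model.feature_importances_, index=model.feature_names_in_)
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)
        assert (imp >= 0).all()
        assert imp[SIGNAL_FEATURES].sum() > 0.9
        # capacity: training fit well below the label spread
        pred = model.predict(X)
        rmse = float(np.sqrt(np.mean((pred - y.to_numpy()) ** 2)))
        assert rmse < 0.25 * float(y.std(ddof=0))
        # training rows recovered closely on the ln-label scale
        rel = np.abs(pred - y.to_numpy()) / np.abs(y.to_numpy())
        assert np.median(rel) < 0.05

    def test_determinism_under_fixed_seed(self, rng):
        X = pd.DataFrame(rng.normal(size=(500, 14)), columns=FEATURE_NAMES)
        y = rng.normal(-4, 1, size=500)
        p1 = VGRegressor(random_state=7).fit(X, y).predict(X)
        p2 = VGRegressor(random_state=7).fit(X, y).predict(X)
        assert np.array_equal(p1, p2)

    def test_schema_mismatch_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 14)), columns=FEATURE_NAMES)
        model = VGRegressor(random_state=0).fit(X, rng.normal(size=50))
        with pytest.raises(ValidationError):
            model.predict(X[list(reversed(FEATURE_NAMES))])

    def test_nonfinite_labels_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 14)), columns=FEATURE_NAMES)
        y = rng.normal(size=20)
        y[3] = np.nan
        with pytest.raises(ValidationError):
            VGRegressor().fit(X, y)

    def test_save_load_round_trip(self, rng, tmp_path):
        X = pd.DataFrame(rng.normal(size=(300, 14)), columns=FEATURE_NAMES)
        y = rng.normal(-4, 1, size=300)
        model = VGRegressor(random_state=1).fit(X, y)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = VGRegressor.load(path)
        assert np.allclose(loaded.predict(X), model.predict(X))
        assert list(loaded.feature_names_in_) == list(model.feature_names_in_)


class TestEvaluate:
    def test_perfect_predictions(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 14)), columns=FEATURE_NAMES)
        y = 2.0 * X["loeuf"].to_numpy()

        class Identity:
            def predict(self, X):
                return 2.0 * X["loeuf"].to_numpy()

        ev = evaluate_model(Identity(), X, y)
        assert ev.rmse_log == pytest.approx(0.0, abs=1e-12)
        assert ev.spearman == pytest.approx(1.0)

    def test_constant_offset_rmse(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 14)), columns=FEATURE_NAMES)
        y = X["loeuf"].to_numpy()

        class Offset:
            def predict(self, X):
                return X["loeuf"].to_numpy() + 0.37

        ev = evaluate_model(Offset(), X, y)
        assert ev.rmse_log == pytest.approx(0.37, rel=1e-12)

    def test_independent_predictions_have_null_spearman(self, rng):
        X = pd.DataFrame(rng.normal(size=(1000, 14)), columns=FEATURE_NAMES)
        y = rng.normal(size=1000)

        class Noise:
            def predict(self, X):
                return np.random.default_rng(99).normal(size=len(X))

        ev = evaluate_model(Noise(), X, y)
        assert abs(ev.spearman) < 0.1


class TestTissueModels:
    def test_disjoint_label_functions_recovered_per_tissue(self, rng):
        n = 1500
        X = pd.DataFrame(rng.normal(size=(n, 14)), columns=FEATURE_NAMES,
                         index=[f"G{i}" for i in range(n)])
        noise = 0.1
        labels = {
            "Brain": pd.Series(1.5 * X["loeuf"] + noise * rng.normal(size=n),
                               index=X.index),
            "Liver": pd.Series(-1.5 * X["tau"] + noise * rng.normal(size=n),
                               index=X.index),
        }
        train = X.index[:1200]
        test = X.index[1200:]
        models = train_tissue_models(
            {t: s.loc[train] for t, s in labels.items()}, X.loc[train], seed=0
        )
        from scipy.stats import spearmanr

        for tissue, model in models.items():
            rho = spearmanr(model.predict(X.loc[test]),
                            labels[tissue].loc[test]).statistic
            assert rho >= 0.9, tissue

    def test_tissue_without_labels_skipped(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 14)), columns=FEATURE_NAMES,
                         index=[f"G{i}" for i in range(200)])
        labels = {
            "Brain": pd.Series(X["loeuf"], index=X.index),
            "Empty": pd.Series(np.nan, index=X.index),
        }
        models = train_tissue_models(labels, X, min_labeled=50, seed=0)
        assert "Brain" in models and "Empty" not in models

    def test_merged_tissue_table_prefers_ae(self):
        # per-tissue AEML equals AE wherever AE exists, ML elsewhere
        frames = {
            ("AE", "Brain"): {"G1": 0.01, "G2": np.nan},
            ("ML", "Brain"): {"G1": 0.09, "G2": 0.05},
        }
        merged = build_vg_table(frames).merge_sources("AE", "ML", "AEML")
        aeml = merged.get("AEML", "Brain")
        assert aeml["G1"] == pytest.approx(0.01)
        assert aeml["G2"] == pytest.approx(0.05)
        # coverage strictly grows when ML predicts an AE-missing gene
        assert aeml.notna().sum() > merged.get("AE", "Brain").notna().sum()
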