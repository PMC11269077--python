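import hashlib

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from chdrisk.evaluate import auc
from chdrisk.risk_model import (MortalityClassifier, drop_sparse_features,
                                encode_features, grid_search_fit, predict_risk,
                                rfe_select, split_train_test)


def planted_signal(n, seed, betas=(1.5, 1.0, 0.8), n_noise=7, intercept=-2.6):
    """Binary outcome driven by a few binary features among pure noise."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({f"inf_{i}": rng.binomial(1, 0.3, n).astype(float)
                      for i in range(len(betas))})
    for i in range(n_noise):
        X[f"noise_{i}"] = rng.standard_normal(n)
    eta = sum(b * X[f"inf_{i}"] for i, b in enumerate(betas)) + intercept
    y = rng.binomial(1, expit(eta))
    return X, y


class TestEncodeFeatures:
    def test_ordinal_ladder_and_onehot(self):
        df = pd.DataFrame({
            "pulmonary_insufficiency": ["negative", "severe", None, "mild"],
            "atrial_shunt": ["none", "two_way", "none", None],
            "age_days": [10.0, 20.0, 30.0, 40.0],
            "died_in_hospital": [0, 1, 0, 0],
        })
        X, y, schema = encode_features(df)
        assert schema["pulmonary_insufficiency"]["encoding"] == "ordinal"
        assert X["pulmonary_insufficiency"].tolist()[:2] == [0.0, 6.0]
        assert np.isnan(X["pulmonary_insufficiency"][2])
        assert X["atrial_shunt=two_way"].tolist()[:2] == [0.0, 1.0]
        assert np.isnan(X["atrial_shunt=none"][3])
        assert y.tolist() == [0, 1, 0, 0]


class TestDropSparseFeatures:
    def _frame(self, frac, n=100):
        x = np.zeros(n)
        x[:int(round(frac * n))] = np.nan
        return pd.DataFrame({"sparse": x, "dense": np.ones(n)})

    def test_above_threshold_dropped(self):
        kept, report = drop_sparse_features(self._frame(0.31))
        assert "sparse" not in kept.columns
        assert report["sparse"] == {"missing_fraction": 0.31, "kept": False}

    def test_exactly_at_threshold_retained(self):
        kept, _ = drop_sparse_features(self._frame(0.30))
        assert "sparse" in kept.columns

    def test_no_missingness_is_identity(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        kept, _ = drop_sparse_features(df)
        pd.testing.assert_frame_equal(kept, df)

    def test_all_dropped_errors(self):
        df = pd.DataFrame({"a": [np.nan, np.nan, 1.0]})
        with pytest.raises(ValueError, match="all features"):
            drop_sparse_features(df)


class TestSplit:
    def test_exact_sizes(self):
        X = pd.DataFrame({"x": np.arange(1000.0)})
        y = np.r_[np.zeros(900), np.ones(100)].astype(int)
        fm = split_train_test(X, y, seed=0)
        assert len(fm.X_train) == 750 and len(fm.X_test) == 250

    def test_cohort_scale_sizes(self):
        X = pd.DataFrame({"x": np.arange(24685.0)})
        y = (np.arange(24685) < 591).astype(int)
        fm = split_train_test(X, y, seed=0)
        assert len(fm.X_train) in (18513, 18514)
        assert len(fm.X_train) + len(fm.X_test) == 24685
        # stratification keeps prevalence matched within one case per split
        assert abs(fm.y_train.sum() - round(0.75 * 591)) <= 1

    def test_same_seed_same_split(self):
        X, y = planted_signal(500, 0)
        a = split_train_test(X, y, seed=3)
        b = split_train_test(X, y, seed=3)
        assert a.X_train.index.equals(b.X_train.index)

    def test_disjoint(self):
        X, y = planted_signal(400, 1)
        fm = split_train_test(X, y, seed=1)
        assert not set(fm.X_train.index) & set(fm.X_test.index)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            split_train_test(pd.DataFrame({"x": [1.0, 2.0]}), np.array([0, 1]))


class TestRfe:
    def test_recovers_planted_informative_features(self):
        X, y = planted_signal(8000, 0)
        trace = rfe_select(X, y, seed=0)
        assert set(trace.selected) == {"inf_0", "inf_1", "inf_2"}
        assert trace.subset_sizes[0] == 10 and trace.subset_sizes[-1] == 1
        # selected subset attains the maximum recorded CV AUC
        assert max(trace.cv_auc) == trace.cv_auc[
            trace.subset_sizes.index(len(trace.selected))]

    def test_duplicated_feature_redundancy(self):
        X, y = planted_signal(4000, 2, betas=(1.5,), n_noise=2)
        X["inf_copy"] = X["inf_0"]
        trace = rfe_select(X, y, seed=0)
        both = {"inf_0", "inf_copy"} <= set(trace.selected)
        one = len({"inf_0", "inf_copy"} & set(trace.selected)) == 1
        if both:
            # dropping the duplicate cannot change discrimination
            i_with = trace.subset_sizes.index(len(trace.selected))
            assert trace.cv_auc[i_with] == pytest.approx(max(trace.cv_auc),
                                                         abs=0.01)
        else:
            assert one

    def test_all_noise_selects_chance_level(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((4000, 6)),
                         columns=[f"n{i}" for i in range(6)])
        y = rng.binomial(1, 0.2, 4000)
        trace = rfe_select(X, y, seed=0)
        best = max(trace.cv_auc)
        assert best == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        X, _ = planted_signal(100, 0)
        with pytest.raises(ValueError, match="single class"):
            rfe_select(X, np.zeros(100, dtype=int))


class TestGridSearch:
    def test_one_point_grid_equals_direct_fit(self):
        X, y = planted_signal(2000, 4)
        grid = {"max_depth": [3]}
        model, best, _ = grid_search_fit(X, y, grid=grid, seed=0)
        assert best == {"max_depth": 3}
        from chdrisk.risk_model import _make_xgb
        direct = _make_xgb(seed=0, y=y).set_params(max_depth=3).fit(X, y)
        assert np.allclose(model.predict_proba(X), direct.predict_proba(X))

    def test_crippled_setting_loses_on_planted_signal(self):
        # a 1-tree stump cannot express a 3-feature additive signal; the
        # crippled corner of the lattice must not win the search
        X, y = planted_signal(4000, 5)
        grid = {"n_estimators": [1, 100], "max_depth": [1, 3]}
        _, best, _ = grid_search_fit(X, y, grid=grid, seed=0)
        assert not (best["n_estimators"] == 1 and best["max_depth"] == 1)

    def test_same_seed_same_choice(self):
        X, y = planted_signal(2000, 6)
        _, a, _ = grid_search_fit(X, y, seed=1)
        _, b, _ = grid_search_fit(X, y, seed=1)
        assert a == b

    def test_auto_pos_weight_resolved(self):
        X, y = planted_signal(2000, 7)
        grid = {"scale_pos_weight": ["auto"]}
        model, best, _ = grid_search_fit(X, y, grid=grid, seed=0)
        assert best["scale_pos_weight"] == pytest.approx((y == 0).sum()
                                                         / (y == 1).sum())


@pytest.fixture(scope="module")
def fitted():
    X, y = planted_signal(6000, 8)
    clf = MortalityClassifier(do_rfe=False, grid={"max_depth": [3]},
                              random_state=0).fit(X, y)
    return clf, X, y


class TestPredictRisk:
    def test_calibration_in_the_large(self, fitted):
        clf, X, y = fitted
        p = clf.predict_proba(X)[:, 1]
        assert p.mean() == pytest.approx(y.mean(), abs=0.01)

    def test_duplicated_row_same_probability(self, fitted):
        clf, X, _ = fitted
        row = X.iloc[[0]]
        two = pd.concat([row, row])
        p = clf.predict_proba(two)[:, 1]
        assert p[0] == p[1]

    def test_probability_bounds_on_extremes(self, fitted):
        clf, X, _ = fitted
        extreme = X.iloc[:4].copy()
        extreme[:] = 1e9
        p = clf.predict_proba(extreme)[:, 1]
        assert np.all((p >= 0) & (p <= 1))

    def test_missing_column_rejected(self, fitted):
        clf, X, _ = fitted
        with pytest.raises(KeyError, match="inf_0"):
            predict_risk(clf.model_, X.drop(columns=["inf_0"]))

    def test_nan_rows_handled_natively(self, fitted):
        clf, X, _ = fitted
        holey = X.iloc[:10].copy()
        holey.iloc[:, 0] = np.nan
        p = clf.predict_proba(holey)[:, 1]
        assert np.all(np.isfinite(p))


class TestMortalityClassifier:
    def test_no_test_set_leakage(self):
        X, y = planted_signal(3000, 9)
        fm = split_train_test(X, y, seed=0)

        def booster_hash(clf):
            raw = clf.model_.get_booster().save_raw(raw_format="json")
            return hashlib.sha256(bytes(raw)).hexdigest()

        clf1 = MortalityClassifier(do_rfe=False, grid={"max_depth": [3]},
                                   random_state=0).fit(fm.X_train, fm.y_train)
        # shuffling the held-out outcomes must not touch the fitted model
        rng = np.random.default_rng(0)
        fm.y_test[:] = rng.permutation(fm.y_test)
        clf2 = MortalityClassifier(do_rfe=False, grid={"max_depth": [3]},
                                   random_state=0).fit(fm.X_train, fm.y_train)
        assert booster_hash(clf1) == booster_hash(clf2)

    def test_importances_normalised(self):
        X, y = planted_signal(3000, 10)
        clf = MortalityClassifier(do_rfe=False, grid={"max_depth": [3]},
                                  random_state=0).fit(X, y)
        assert clf.feature_importances_.sum() == pytest.approx(1.0)
        assert (clf.feature_importances_ >= 0).all()

    def test_sparse_feature_removed_before_modeling(self):
        X, y = planted_signal(2000, 11)
        X["mostly_missing"] = np.nan
        X.loc[:300, "mostly_missing"] = 1.0
        clf = MortalityClassifier(do_rfe=False, grid={"max_depth": [3]},
                                  random_state=0).fit(X, y)
        assert "mostly_missing" not in clf.features_

    def test_sklearn_get_set_params_roundtrip(self):
        clf = MortalityClassifier(cv=3, random_state=5)
        params = clf.get_params()
        assert params["cv"] == 3
        clone = MortalityClassifier(**params)
        assert clone.get_params() == params
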