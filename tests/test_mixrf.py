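import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

from amuplan.mixrf import MixedForest, MixRFConfig, fit_mixrf
from amuplan.preprocess import preprocess
from amuplan.synthetic import (country_intercepts, generate_farms,
                               recovery_config)

from conftest import FAST_MIXRF


class TestFit:
    def test_single_group_reduces_to_plain_forest(self, tiny_data):
        X, y, _ = tiny_data
        groups = np.array(["only"] * len(y))
        res = fit_mixrf(X, y, groups, config=MixRFConfig(**FAST_MIXRF))
        assert res.sigma2_b == 0.0
        plain = RandomForestRegressor(
            n_estimators=30, max_features=X.shape[1] // 3,
            min_samples_leaf=5, random_state=7, n_jobs=1).fit(X, y)
        np.testing.assert_allclose(
            res.predict(X, groups), plain.predict(X), atol=1e-12)

    def test_intercepts_recover_planted_values(self):
        cfg = recovery_config(seed=21, n_features=8)
        table = generate_farms(cfg)
        X, y, groups, _, _ = preprocess(table)
        res = fit_mixrf(X, y, groups,
                        config=MixRFConfig(n_trees=100, max_em_iter=10,
                                           seed=0))
        planted = country_intercepts(cfg)
        est = res.random_effects
        corr = np.corrcoef([planted[c] for c in est.index], est.values)[0, 1]
        assert corr > 0.9
        assert len(est) == 9

    def test_duplicated_farms_get_identical_fitted_values(self, tiny_data):
        X, y, groups = tiny_data
        X2 = pd.concat([X, X.iloc[[0]]], ignore_index=True)
        y2 = np.r_[y, y[0]]
        g2 = np.concatenate([groups, [groups[0]]])
        res = fit_mixrf(X2, y2, g2, config=MixRFConfig(**FAST_MIXRF))
        fitted = res.predict(X2, g2)
        assert fitted[0] == pytest.approx(fitted[-1], abs=1e-12)

    def test_constant_outcome_warns(self, tiny_data):
        X, _, groups = tiny_data
        with pytest.warns(RuntimeWarning, match="constant"):
            fit_mixrf(X, np.ones(len(X)), groups,
                      config=MixRFConfig(**FAST_MIXRF))

    def test_em_trace_finite_and_contracting(self, tiny_fit):
        trace = tiny_fit.em_trace
        assert len(trace) >= 1
        assert all(np.isfinite(list(t.values())).all() is not False
                   for t in trace)
        deltas = [t["max_delta"] for t in trace[1:]]
        if len(deltas) >= 2:
            assert deltas[-1] <= deltas[0]

    def test_variance_components_nonnegative(self, tiny_fit):
        assert tiny_fit.sigma2_b >= 0 and tiny_fit.sigma2_e >= 0

    def test_misaligned_rows_rejected(self, tiny_data):
        X, y, groups = tiny_data
        with pytest.raises(ValueError, match="aligned"):
            MixedForest(y[:-1], X, groups)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MixRFConfig(n_trees=0).validate()
        with pytest.raises(ValueError):
            MixRFConfig(mtry=99).resolve_mtry(5)


class TestPredict:
    def test_unknown_country_equals_fixed_part(self, tiny_fit, tiny_data):
        X, _, _ = tiny_data
        with_unknown = tiny_fit.predict(X, np.array(["ZZ"] * len(X)))
        without = tiny_fit.predict(X, include_random=False)
        np.testing.assert_allclose(with_unknown, without)

    def test_known_country_adds_intercept(self, tiny_fit, tiny_data):
        X, _, groups = tiny_data
        a = tiny_fit.predict(X.iloc[[0]], groups[[0]])
        b = tiny_fit.predict(X.iloc[[0]], include_random=False)
        expected = tiny_fit.random_effects[groups[0]]
        assert a[0] - b[0] == pytest.approx(expected)

    def test_column_mismatch_rejected(self, tiny_fit, tiny_data):
        X, _, _ = tiny_data
        with pytest.raises(ValueError, match="columns"):
            tiny_fit.predict(X[list(X.columns)[::-1]])

    def test_flip_direction_matches_planted_sign(self):
        """On a noise-free planted design, flipping a feature moves the
        prediction in the planted direction (oracle: ground truth)."""
        cfg = recovery_config(seed=5, n_features=6, sigma_noise=0.0)
        table = generate_farms(cfg)
        X, y, groups, _, _ = preprocess(table)
        res = fit_mixrf(X, y, groups,
                        config=MixRFConfig(n_trees=100, seed=0))
        base = res.predict(X, include_random=False).mean()
        for feat, sign in (("q_001", 1), ("q_002", -1)):
            X1 = X.copy()
            X1[feat] = 1.0
            X0 = X.copy()
            X0[feat] = 0.0
            delta = res.predict(X1, include_random=False).mean() \
                - res.predict(X0, include_random=False).mean()
            assert np.sign(delta) == sign
        assert np.isfinite(base)


class TestImportanceAndProximity:
    def test_importances_sum_to_one(self, tiny_fit):
        assert tiny_fit.feature_importances().sum() == pytest.approx(1.0)

    def test_planted_features_dominate(self, tiny_fit):
        top2 = set(tiny_fit.feature_importances()
                   .sort_values(ascending=False).index[:2])
        assert {"q_001", "q_002"} == top2

    def test_proximity_invariants(self, tiny_fit, tiny_data):
        X, _, _ = tiny_data
        P = tiny_fit.proximity(X)
        np.testing.assert_allclose(P, P.T)
        np.testing.assert_allclose(np.diag(P), 1.0)
        assert P.min() >= 0 and P.max() <= 1
        # entries are multiples of 1/n_trees
        np.testing.assert_allclose(P * 30, np.round(P * 30), atol=1e-9)

    def test_duplicated_row_proximity_one(self, tiny_fit, tiny_data):
        X, _, _ = tiny_data
        Xdup = pd.concat([X.iloc[[0]], X.iloc[[0]]], ignore_index=True)
        P = tiny_fit.proximity(Xdup)
        assert P[0, 1] == 1.0

    def test_toy_forest_matches_hand_count(self):
        """Proximity on a 3-tree depth-1 forest over 5 farms equals an
        independent per-pair per-tree leaf count."""
        rng = np.random.default_rng(0)
        Xt = rng.random((5, 2))
        yt = rng.random(5)
        forest = RandomForestRegressor(n_estimators=3, max_depth=1,
                                       random_state=0).fit(Xt, yt)
        leaves = forest.apply(Xt)
        expected = np.empty((5, 5))
        for i in range(5):
            for j in range(5):
                expected[i, j] = sum(
                    leaves[i, t] == leaves[j, t] for t in range(3)) / 3
        res_like = fit_mixrf(pd.DataFrame(Xt, columns=["a", "b"]), yt,
                             np.array(["g"] * 5),
                             config=MixRFConfig(n_trees=3, seed=0,
                                                min_samples_leaf=1))
        res_like.forest = forest  # compare the proximity routine itself
        res_like.exog_names = ["a", "b"]
        P = res_like.proximity(pd.DataFrame(Xt, columns=["a", "b"]))
        np.testing.assert_allclose(P, expected)


def test_save_load_round_trip(tmp_path, tiny_fit, tiny_data):
    X, _, groups = tiny_data
    path = tmp_path / "model.joblib"
    tiny_fit.save(path)
    from amuplan.mixrf import MixedForestResults
    loaded = MixedForestResults.load(path)
    np.testing.assert_allclose(loaded.predict(X, groups),
                               tiny_fit.predict(X, groups))


def test_summary_contains_key_quantities(tiny_fit):
    text = tiny_fit.summary()
    assert "sigma2 (country)" in text and "Gini importance" in text
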