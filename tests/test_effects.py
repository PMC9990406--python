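import numpy as np
import pandas as pd
import pytest

from amuplan.effects import (StrengthWeakness, bootstrap_ci, classify,
                             filter_by_expectation, impute_missing_levels,
                             load_expectations, partial_effect)
from amuplan.mixrf import MixRFConfig, fit_mixrf
from amuplan.preprocess import MISSING_LEVEL, preprocess
from amuplan.synthetic import SyntheticConfig, generate_farms, ground_truth

from conftest import FAST_MIXRF


class TestImpute:
    def test_no_missing_returns_unchanged(self, tiny_data):
        X, _, _ = tiny_data
        out = impute_missing_levels(X, seed=0)
        pd.testing.assert_frame_equal(out, X)

    def test_imputed_values_binary(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({
            "q_001": rng.integers(0, 2, 80).astype(float),
            "q_002": rng.integers(0, 2, 80).astype(float),
        })
        X.iloc[:10, 0] = MISSING_LEVEL
        out = impute_missing_levels(X, seed=0)
        assert set(out["q_001"].unique()) <= {0.0, 1.0}

    def test_beats_majority_baseline_with_strong_predictor(self):
        """Mask-and-recover: when one answer nearly determines another,
        chained-equation imputation must beat the mode fill."""
        rng = np.random.default_rng(1)
        n = 200
        truth = rng.integers(0, 2, n).astype(float)
        noisy_copy = np.where(rng.random(n) < 0.05, 1 - truth, truth)
        X = pd.DataFrame({"q_001": truth.copy(), "q_002": noisy_copy,
                          "q_003": rng.integers(0, 2, n).astype(float)})
        mask = rng.random(n) < 0.2
        X.loc[mask, "q_001"] = MISSING_LEVEL
        out = impute_missing_levels(X, seed=1)
        acc = (out.loc[mask, "q_001"] == truth[mask]).mean()
        majority = max(truth[~mask].mean(), 1 - truth[~mask].mean())
        assert acc > majority

    def test_entirely_missing_rejected(self):
        X = pd.DataFrame({"q_001": [MISSING_LEVEL] * 5,
                          "q_002": [0.0, 1, 0, 1, 0]})
        with pytest.raises(ValueError, match="entirely missing"):
            impute_missing_levels(X)


class TestPartialEffect:
    def test_equals_brute_force(self, tiny_fit, tiny_data):
        """The forced-dataset average must equal a per-row counterfactual
        loop (the definition, computed independently)."""
        X, _, _ = tiny_data
        for feat in ("q_001", "q_003"):
            diffs = []
            for i in range(len(X)):
                r1 = X.iloc[[i]].copy()
                r1[feat] = 1.0
                r0 = X.iloc[[i]].copy()
                r0[feat] = 0.0
                diffs.append(
                    tiny_fit.predict(r1, include_random=False)[0]
                    - tiny_fit.predict(r0, include_random=False)[0])
            assert partial_effect(tiny_fit, X, feat) == \
                pytest.approx(np.mean(diffs), abs=1e-12)

    def test_unused_feature_has_zero_effect(self, tiny_data):
        X, y, groups = tiny_data
        X = X.copy()
        X["q_const"] = 1.0  # constant -> never split on
        res = fit_mixrf(X, y, groups, config=MixRFConfig(**FAST_MIXRF))
        assert partial_effect(res, X, "q_const") == 0.0

    def test_signs_match_planted_effects(self, tiny_fit, tiny_data):
        X, _, _ = tiny_data
        truth = ground_truth(SyntheticConfig(
            n_features=6, true_effects={"q_001": 0.8, "q_002": -0.8}))
        assert np.sign(partial_effect(tiny_fit, X, "q_001")) == \
            np.sign(truth["q_001"])
        assert np.sign(partial_effect(tiny_fit, X, "q_002")) == \
            np.sign(truth["q_002"])


class TestBootstrapCI:
    @pytest.fixture(scope="class")
    def data(self):
        cfg = SyntheticConfig(n_countries=5, farms_per_country=12,
                              n_features=4,
                              true_effects={"q_001": 0.8},
                              sigma_country=0.3, sigma_noise=0.2,
                              zero_inflation=0.0, seed=3)
        table = generate_farms(cfg)
        X, y, groups, _, _ = preprocess(table)
        return X, y, groups

    def test_deterministic_under_seed(self, data):
        X, y, groups = data
        kw = dict(mixrf_config=MixRFConfig(n_trees=10, max_em_iter=1),
                  n_boot=15, seed=5)
        assert bootstrap_ci(X, y, groups, "q_001", **kw) == \
            bootstrap_ci(X, y, groups, "q_001", **kw)

    def test_percentile_definition(self, data):
        X, y, groups = data
        lo, hi, samples = bootstrap_ci(
            X, y, groups, "q_001",
            mixrf_config=MixRFConfig(n_trees=10, max_em_iter=1),
            n_boot=40, seed=2, return_samples=True)
        assert lo == pytest.approx(np.percentile(samples, 2.5))
        assert hi == pytest.approx(np.percentile(samples, 97.5))
        assert lo <= hi

    def test_strong_effect_excludes_zero(self, data):
        X, y, groups = data
        lo, hi = bootstrap_ci(
            X, y, groups, "q_001",
            mixrf_config=MixRFConfig(n_trees=30, max_em_iter=2),
            n_boot=40, seed=1)
        assert lo > 0

    def test_small_n_boot_rejected(self, data):
        X, y, groups = data
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_ci(X, y, groups, "q_001", n_boot=5)


class TestClassify:
    @pytest.mark.parametrize("value,effect,label", [
        (1, -0.3, "strength"),
        (0, +0.3, "strength"),
        (1, +0.3, "weakness"),
        (0, -0.3, "weakness"),
    ])
    def test_cross_table(self, value, effect, label):
        out = classify({"f": value}, {"f": effect})
        assert len(out) == 1
        assert out[0].label == label
        assert out[0].effect_sign == ("-" if effect < 0 else "+")

    def test_zero_effect_skipped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="exactly 0"):
            out = classify({"f": 1}, {"f": 0.0})
        assert out == []

    def test_non_binary_value_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            classify({"f": 2}, {"f": 0.5})


class TestExpectationFilter:
    def test_matching_protective_kept(self):
        w = [StrengthWeakness("hygiene_lock", 0, "-", "weakness")]
        kept = filter_by_expectation(w, {"hygiene_lock": -0.4},
                                     {"hygiene_lock": "protective"})
        assert kept == ["hygiene_lock"]

    def test_sign_mismatch_dropped(self):
        w = [StrengthWeakness("vaccination_protocol_non_official", 1, "+",
                              "weakness")]
        kept = filter_by_expectation(
            w, {"vaccination_protocol_non_official": 0.4},
            {"vaccination_protocol_non_official": "protective"})
        assert kept == []

    def test_unclear_dropped(self):
        w = [StrengthWeakness("visitor_check_in", 1, "+", "weakness")]
        kept = filter_by_expectation(w, {"visitor_check_in": 0.4},
                                     {"visitor_check_in": "unclear"})
        assert kept == []

    def test_unlisted_dropped_with_warning(self):
        w = [StrengthWeakness("q_099", 0, "-", "weakness")]
        with pytest.warns(RuntimeWarning, match="no biological"):
            kept = filter_by_expectation(w, {"q_099": -0.2}, {})
        assert kept == []

    def test_risky_with_positive_effect_kept(self):
        w = [StrengthWeakness("depopulation_two_or_more_steps", 1, "+",
                              "weakness")]
        kept = filter_by_expectation(
            w, {"depopulation_two_or_more_steps": 0.5},
            {"depopulation_two_or_more_steps": "risky"})
        assert kept == ["depopulation_two_or_more_steps"]


def test_packaged_expectations_load_and_validate():
    table = load_expectations()
    assert table["hygiene_lock"] == "protective"
    assert table["depopulation_two_or_more_steps"] == "risky"
    assert all(v in {"protective", "risky", "unclear"}
               for v in table.values())
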