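"""Effect sizes, strength/weakness classification and expectation matching.

The effect size of a binary biosecurity answer is its partial-dependence
contrast: the model's mean prediction with the answer forced to 1 on every
farm minus the mean with it forced to 0, all other columns untouched — the
average effect of a one-unit change while marginalising over the rest.
Uncertainty comes from a nonparametric farm-level bootstrap (resampling
within country so the intercepts stay estimable).

Before effects are computed, any remaining "missing" third level of a
binary answer is imputed to 0/1 by chained equations with random-forest
classifiers (a single-imputation MICE).

A farm's *strengths* are measures it applies that lower predicted usage
(or doesn't apply and that raise it); *weaknesses* are the complementary
cells of that 2x2 table and form the candidate interventions, which are
then screened against a table of expected biological directions —
an estimated sign that contradicts the measure's known mechanism (e.g. a
vaccination protocol apparently raising usage, a classic reverse-causality
signature in cross-sectional data) disqualifies the measure from planning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from sklearn.ensemble import RandomForestClassifier

from .mixrf import MixRFConfig, MixedForestResults, fit_mixrf
from .preprocess import MISSING_LEVEL

logger = logging.getLogger(__name__)


@dataclass
class EffectEstimate:
    feature: str
    effect: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_boot: int = 0
    sign_consistency: int = 0


@dataclass
class StrengthWeakness:
    feature: str
    farm_value: int
    effect_sign: str  # "+" or "-"
    label: str        # "strength" or "weakness"


def impute_missing_levels(X: pd.DataFrame, binary_features=None,
                          seed: int = 0, n_sweeps: int = 5) -> pd.DataFrame:
    """Replace the missing third level of binary answers with 0/1.

    Chained equations with a random-forest classifier per incomplete
    column: missing cells are initialised to the column mode, then each
    incomplete column in turn is re-predicted from all other columns for
    ``n_sweeps`` sweeps.  Deterministic under ``seed``.
    """
    if binary_features is None:
        binary_features = [c for c in X.columns if c.startswith("q_")]
    X = X.copy()
    missing = {}
    for f in binary_features:
        mask = (X[f] == MISSING_LEVEL) | X[f].isna()
        if mask.all():
            raise ValueError(f"feature {f!r} is entirely missing; cannot "
                             "impute")
        if mask.any():
            missing[f] = mask.to_numpy()
    if not missing:
        return X
    # initialise with the observed mode
    for f, mask in missing.items():
        observed = X.loc[~mask, f]
        mode = 1.0 if (observed == 1).sum() >= (observed == 0).sum() else 0.0
        X.loc[mask, f] = mode
    for sweep in range(n_sweeps):
        for j, (f, mask) in enumerate(missing.items()):
            others = [c for c in X.columns if c != f]
            clf = RandomForestClassifier(
                n_estimators=30, min_samples_leaf=2,
                random_state=seed + 1000 * sweep + j, n_jobs=1)
            obs = ~mask
            yobs = X.loc[obs, f].astype(int)
            if yobs.nunique() < 2:
                continue  # observed part constant; keep mode fill
            clf.fit(X.loc[obs, others].to_numpy(dtype=float), yobs)
            pred = clf.predict(X.loc[mask, others].to_numpy(dtype=float))
            X.loc[mask, f] = pred.astype(float)
    return X


def partial_effect(results: MixedForestResults, X: pd.DataFrame,
                   feature: str) -> float:
    """Partial-dependence effect of a binary answer.

    Mean prediction over all farms with ``feature`` forced to 1 minus the
    mean with it forced to 0 (forest part only; the country intercepts
    cancel in the difference).
    """
    if feature not in X.columns:
        raise KeyError(f"feature {feature!r} not in the model matrix")
    X1 = X.copy()
    X1[feature] = 1.0
    X0 = X.copy()
    X0[feature] = 0.0
    return float(np.mean(results.predict(X1, include_random=False))
                 - np.mean(results.predict(X0, include_random=False)))


def bootstrap_ci(X: pd.DataFrame, y, groups, feature: str,
                 mixrf_config: MixRFConfig | None = None,
                 n_boot: int = 1000, level: float = 0.95,
                 seed: int = 0, return_samples: bool = False):
    """Percentile bootstrap CI for a feature's partial-dependence effect.

    Farms are resampled with replacement within their country (stratified
    bootstrap), the mixed forest is refitted, and the effect recomputed;
    the interval is the (1-level)/2 and 1-(1-level)/2 percentiles.
    """
    if n_boot < 10:
        raise ValueError("n_boot must be >= 10 for a meaningful interval")
    if mixrf_config is None:
        mixrf_config = MixRFConfig()
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    by_country = {c: np.flatnonzero(groups == c) for c in np.unique(groups)}
    effects = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(ix, size=len(ix), replace=True)
                              for ix in by_country.values()])
        cfg = MixRFConfig(**{**mixrf_config.__dict__,
                             "seed": mixrf_config.seed + b + 1})
        res = fit_mixrf(X.iloc[idx], y[idx], groups[idx], config=cfg)
        effects[b] = partial_effect(res, X, feature)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(effects, [100 * alpha, 100 * (1 - alpha)])
    if return_samples:
        return float(lo), float(hi), effects
    return float(lo), float(hi)


def classify(farm_values, effects) -> list:
    """Strength/weakness classification of a farm's answers.

    ``farm_values`` maps feature -> 0/1 (post-imputation); ``effects``
    maps feature -> signed effect.  Applied + negative effect or
    not-applied + positive effect = strength; the complementary cells are
    weaknesses (the candidate action points).  Zero effects are skipped
    with a warning.
    """
    if isinstance(effects, dict):
        eff_map = effects
    else:
        eff_map = {e.feature: e.effect for e in effects}
    out = []
    for feat, value in farm_values.items():
        if feat not in eff_map:
            continue
        eff = eff_map[feat]
        if eff == 0:
            warnings.warn(f"effect of {feat!r} is exactly 0; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        if value not in (0, 1):
            raise ValueError(f"farm value for {feat!r} must be 0/1 after "
                             f"imputation, got {value!r}")
        sign = "-" if eff < 0 else "+"
        strength = (value == 1 and eff < 0) or (value == 0 and eff > 0)
        out.append(StrengthWeakness(feat, int(value), sign,
                                    "strength" if strength else "weakness"))
    return out


def load_expectations(path=None) -> dict:
    """Expectation table: feature -> protective | risky | unclear.

    Without a path, the packaged default table is loaded.
    """
    if path is None:
        text = (resources.files("amuplan.data") / "expectations.yaml")\
            .read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table = yaml.safe_load(text)
    allowed = {"protective", "risky", "unclear"}
    for feat, direction in table.items():
        if direction not in allowed:
            raise ValueError(f"expectation for {feat!r} must be one of "
                             f"{sorted(allowed)}, got {direction!r}")
    return table


def filter_by_expectation(weaknesses: list, effects,
                          expectations: dict) -> list:
    """Keep only weaknesses whose estimated sign matches biology.

    protective <-> negative effect of applying; risky <-> positive.
    'unclear' and unlisted features are dropped (the latter with a
    warning) — they remain predictors but not intervention candidates.
    """
    if isinstance(effects, dict):
        eff_map = effects
    else:
        eff_map = {e.feature: e.effect for e in effects}
    kept = []
    for w in weaknesses:
        if w.label != "weakness":
            continue
        if w.feature not in expectations:
            warnings.warn(f"no biological expectation for {w.feature!r}; "
                          "dropped from candidates", RuntimeWarning,
                          stacklevel=2)
            continue
        expected = expectations[w.feature]
        if expected == "unclear":
            continue
        eff = eff_map[w.feature]
        if (expected == "protective" and eff < 0) or \
           (expected == "risky" and eff > 0):
            kept.append(w.feature)
    return kept
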