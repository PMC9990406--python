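"""Random-forest recursive feature elimination (RF-RFE) with k-fold CV.

Procedure
---------
1. Split farms into k folds, stratified by country so every training split
   contains every country (needed to estimate the random intercepts).
2. Within each fold's training split, fit the mixed-effects forest on all
   features and repeatedly drop the single least Gini-important feature,
   refitting after each drop, until ``floor(keep_fraction * p0)`` remain
   (25% of 53 features keeps 13).
3. Count, across folds, how often each feature survived; form the nested
   subsets "appeared in >= t folds" for t = 1..k.
4. Score each subset by refitting on every fold's training split and
   averaging test-split RMSE (transformed scale); the subset with the
   lowest mean RMSE wins, ties broken toward the sparser subset.

During the within-fold elimination loop the country intercepts estimated on
the full feature set are held fixed (the intercept structure belongs to the
countries, not the candidate subset); subset scoring in step 4 refits the
full mixed model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import StratifiedKFold

from .mixrf import MixRFConfig, fit_mixrf

logger = logging.getLogger(__name__)


@dataclass
class RFEConfig:
    k_folds: int = 10
    keep_fraction: float = 0.25
    seed: int = 0

    def validate(self, n: int):
        if not 2 <= self.k_folds <= n:
            raise ValueError(f"k_folds must be in [2, {n}]")
        if not 0.0 < self.keep_fraction < 1.0:
            raise ValueError("keep_fraction must be in (0, 1)")


@dataclass
class RFEResult:
    fold_subsets: list
    feature_frequencies: dict
    threshold_subsets: dict
    mean_rmse: dict
    selected_threshold: int
    final_features: list

    def to_dict(self):
        return {
            "fold_subsets": [list(s) for s in self.fold_subsets],
            "feature_frequencies": dict(self.feature_frequencies),
            "threshold_subsets": {int(t): list(s)
                                  for t, s in self.threshold_subsets.items()},
            "mean_rmse": {int(t): float(v)
                          for t, v in self.mean_rmse.items()},
            "selected_threshold": int(self.selected_threshold),
            "final_features": list(self.final_features),
        }


def rmse(y, yhat) -> float:
    """Root mean squared error; symmetric under joint permutation."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    if y.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def n_keep(p0: int, keep_fraction: float) -> int:
    """Number of features the elimination loop retains: floor(f * p0)."""
    k = math.floor(keep_fraction * p0)
    if k < 1:
        raise ValueError(f"keep target floor({keep_fraction} * {p0}) < 1; "
                         "raise keep_fraction or supply more features")
    return k


def eliminate_within_fold(X_train: pd.DataFrame, y_train, groups_train,
                          keep_fraction: float = 0.25,
                          config: MixRFConfig | None = None) -> list:
    """Backward elimination to the top ``keep_fraction`` of features.

    Fits the mixed-effects forest once on all features to estimate the
    country intercepts, then repeatedly refits the forest on the
    intercept-adjusted outcome, dropping the single least important feature
    per refit, until ``floor(keep_fraction * p0)`` features remain.
    """
    if config is None:
        config = MixRFConfig()
    p0 = X_train.shape[1]
    if p0 < 2:
        raise ValueError("need at least 2 features to eliminate")
    target = n_keep(p0, keep_fraction)

    res = fit_mixrf(X_train, y_train, groups_train, config=config)
    offsets = (pd.Series(np.asarray(groups_train))
               .map(res.random_effects).fillna(0.0).to_numpy())
    y_adj = np.asarray(y_train, dtype=float) - offsets

    current = list(X_train.columns)
    imp = res.feature_importances()
    while len(current) > target:
        worst = imp.idxmin()  # first occurrence on ties: deterministic
        current.remove(worst)
        rf = RandomForestRegressor(
            n_estimators=config.n_trees,
            max_features=config.resolve_mtry(len(current)),
            min_samples_leaf=config.min_samples_leaf,
            random_state=config.seed, n_jobs=1)
        rf.fit(X_train[current].to_numpy(dtype=float), y_adj)
        imp = pd.Series(rf.feature_importances_, index=current)
    return current


def make_folds(groups, k_folds: int, seed: int):
    """Country-stratified fold assignment; returns (train_idx, test_idx)
    pairs partitioning the farms."""
    groups = np.asarray(groups)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(groups)), groups))


def select_threshold(mean_rmse: dict) -> int:
    """Threshold with the lowest mean RMSE; ties go to the larger t
    (sparser model)."""
    best = min(mean_rmse.items(), key=lambda kv: (kv[1], -kv[0]))
    return int(best[0])


def run_rfe(X: pd.DataFrame, y, groups, config: RFEConfig | None = None,
            mixrf_config: MixRFConfig | None = None) -> RFEResult:
    """Full RF-RFE: per-fold elimination, frequency subsets, RMSE-based
    subset selection.  See the module docstring for the steps."""
    if config is None:
        config = RFEConfig()
    if mixrf_config is None:
        mixrf_config = MixRFConfig()
    y = np.asarray(y, dtype=float)
    config.validate(len(y))
    folds = make_folds(groups, config.k_folds, config.seed)
    groups = np.asarray(groups)

    fold_subsets = []
    for train_idx, _ in folds:
        subset = eliminate_within_fold(
            X.iloc[train_idx], y[train_idx], groups[train_idx],
            keep_fraction=config.keep_fraction, config=mixrf_config)
        fold_subsets.append(subset)

    freq = {f: 0 for f in X.columns}
    for subset in fold_subsets:
        for f in subset:
            freq[f] += 1

    threshold_subsets = {}
    for t in range(1, config.k_folds + 1):
        subset = [f for f in X.columns if freq[f] >= t]
        if subset:
            threshold_subsets[t] = subset

    # score each distinct (fold, subset) combination once
    cache: dict = {}

    def fold_rmse(fold_i, subset_key):
        key = (fold_i, subset_key)
        if key not in cache:
            train_idx, test_idx = folds[fold_i]
            cols = list(subset_key)
            res = fit_mixrf(X.iloc[train_idx][cols], y[train_idx],
                            groups[train_idx], config=mixrf_config)
            pred = res.predict(X.iloc[test_idx][cols],
                               groups=groups[test_idx])
            cache[key] = rmse(y[test_idx], pred)
        return cache[key]

    mean_rmse = {}
    for t, subset in threshold_subsets.items():
        key = tuple(subset)
        mean_rmse[t] = float(np.mean(
            [fold_rmse(i, key) for i in range(len(folds))]))

    selected = select_threshold(mean_rmse)
    result = RFEResult(fold_subsets, freq, threshold_subsets, mean_rmse,
                       selected, threshold_subsets[selected])
    logger.info("RF-RFE selected threshold %d/%d with %d features "
                "(mean RMSE %.4f)", selected, config.k_folds,
                len(result.final_features), mean_rmse[selected])
    return result


def importance_contribution_flags(importances, n_features: int | None = None):
    """Flag features whose share of total Gini importance exceeds the
    heuristic limit 1/N (N = number of features in the model).

    Returns ``(flags, threshold_pct)`` where ``threshold_pct`` is the limit
    as a percentage truncated to 1 d.p. (N = 21 gives 4.7%); the flags
    themselves use the exact 1/N share.
    """
    imp = pd.Series(importances, dtype=float)
    if n_features is None:
        n_features = len(imp)
    total = imp.sum()
    share = imp / total if total > 0 else imp * 0.0
    threshold = 1.0 / n_features
    flags = share > threshold
    return flags, math.floor(threshold * 1000.0) / 10.0
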