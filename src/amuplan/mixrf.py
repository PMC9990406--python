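"""Mixed-effects random forest (Mix-RF) for grouped farm data.

Model
-----
For farm *i* in country *c*::

    y_ic = f(x_ic) + b_c + eps_ic,   b_c ~ N(0, sigma2_b),  eps ~ N(0, sigma2_e)

where ``f`` is a regression forest and ``b_c`` a country-level random
intercept.  Fitting alternates, EM-style:

(a) fit the forest to ``y - b`` (current intercepts removed);
(b) form out-of-bag residuals ``r = y - f_oob(x)`` and update the
    intercepts as their shrunken (BLUP) group means;
(c) update the variance components ``sigma2_b`` and ``sigma2_e``;

until the largest intercept change falls below ``em_tol`` or ``max_em_iter``
is reached, or the update stalls (refitting the forest perturbs the
out-of-bag residuals by a roughly constant amount, so once the intercept
change stops shrinking further iterations only chase noise).  Out-of-bag
predictions are used in (b) so the intercepts are estimated from residual
signal the forest has not memorised.

The module follows the statsmodels convention: :class:`MixedForest` is the
model specification, :meth:`MixedForest.fit` returns a
:class:`MixedForestResults` carrying estimates, diagnostics, ``predict``,
``feature_importances``, ``proximity`` and ``summary``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-12


@dataclass
class MixRFConfig:
    """Tuning knobs of the mixed-effects forest.

    ``mtry=None`` means the regression-forest default floor(p/3).
    ``min_samples_leaf=5`` mirrors the classical regression-forest leaf
    size.  ``max_em_iter``/``em_tol`` bound the intercept-update loop.
    """

    n_trees: int = 500
    mtry: int | None = None
    max_em_iter: int = 50
    em_tol: float = 1e-4
    min_samples_leaf: int = 5
    seed: int = 0

    def resolve_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else max(1, p // 3)
        if not 1 <= m <= p:
            raise ValueError(f"mtry must be in [1, {p}], got {m}")
        return m

    def validate(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_em_iter < 1:
            raise ValueError("max_em_iter must be >= 1")
        if self.em_tol <= 0:
            raise ValueError("em_tol must be > 0")


class MixedForest:
    """Mixed-effects random forest model specification.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Outcome on the transformed (started-log TIDDDvet) scale.
    exog : DataFrame or ndarray, shape (n, p)
        Model matrix; column order is frozen at fit time.
    groups : array-like, shape (n,)
        Country (cluster) labels.
    config : MixRFConfig, optional
        Tuning parameters; keyword arguments override single fields.
    """

    def __init__(self, endog, exog, groups, config: MixRFConfig | None = None,
                 **kwargs):
        if config is None:
            config = MixRFConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either a config or keyword overrides, "
                            "not both")
        config.validate()
        self.config = config
        if isinstance(exog, pd.DataFrame):
            self.exog_names = list(exog.columns)
            self._X = exog.to_numpy(dtype=float)
        else:
            self._X = np.asarray(exog, dtype=float)
            self.exog_names = [f"x{i}" for i in range(self._X.shape[1])]
        self._y = np.asarray(endog, dtype=float)
        self._groups = np.asarray(groups)
        if not (len(self._y) == len(self._X) == len(self._groups)):
            raise ValueError("endog, exog and groups must be row-aligned")
        if len(self._y) == 0:
            raise ValueError("empty training data")

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "MixedForestResults":
        cfg = self.config
        X, y, groups = self._X, self._y, self._groups
        n, p = X.shape
        codes, uniques = pd.factorize(groups)
        n_groups = len(uniques)
        counts = np.bincount(codes, minlength=n_groups).astype(float)

        if np.ptp(y) == 0:
            warnings.warn("outcome is constant; variance components are "
                          "zero and the forest is degenerate",
                          RuntimeWarning, stacklevel=2)

        single_group = n_groups < 2
        b = np.zeros(n_groups)
        sigma2_b = 0.0 if single_group else max(float(np.var(y)) / 2,
                                                _VAR_FLOOR)
        sigma2_e = max(float(np.var(y)) / 2, _VAR_FLOOR)
        trace = []
        forest = None
        for it in range(cfg.max_em_iter):
            target = y - b[codes]
            forest = RandomForestRegressor(
                n_estimators=cfg.n_trees,
                max_features=cfg.resolve_mtry(p),
                min_samples_leaf=cfg.min_samples_leaf,
                oob_score=True, bootstrap=True,
                random_state=cfg.seed, n_jobs=1)
            with warnings.catch_warnings():
                warnings.filterwarnings(
                    "ignore", message=".*in-bag.*|.*OOB.*|.*oob.*")
                forest.fit(X, target)
            oob = np.asarray(forest.oob_prediction_, dtype=float)
            bad = ~np.isfinite(oob)
            if bad.any():  # rows never out of bag (tiny forests only)
                oob[bad] = forest.predict(X[bad])
            r = y - oob  # approx b_g + eps
            if single_group:
                b_new = b
                sigma2_e = max(float(np.mean(r ** 2)), _VAR_FLOOR)
                trace.append({"iter": it, "sigma2_b": 0.0,
                              "sigma2_e": sigma2_e, "max_delta": 0.0})
                break
            # posterior (BLUP) mean and variance of each intercept
            v = 1.0 / (counts / sigma2_e + 1.0 / max(sigma2_b, _VAR_FLOOR))
            m = v * np.bincount(codes, weights=r,
                                minlength=n_groups) / sigma2_e
            sigma2_b = max(float(np.mean(m ** 2 + v)), _VAR_FLOOR)
            resid = r - m[codes]
            sigma2_e = max(float(np.mean(resid ** 2) +
                                 np.mean(v[codes])), _VAR_FLOOR)
            delta = float(np.max(np.abs(m - b)))
            b = m
            prev_delta = trace[-1]["max_delta"] if trace else np.inf
            trace.append({"iter": it, "sigma2_b": sigma2_b,
                          "sigma2_e": sigma2_e, "max_delta": delta})
            if delta < cfg.em_tol:
                break
            if it >= 2 and delta >= 0.95 * prev_delta:
                break  # stalled at the out-of-bag noise floor

        intercepts = pd.Series(b, index=uniques, name="random_intercept")
        return MixedForestResults(self, forest, intercepts,
                                  0.0 if single_group else sigma2_b,
                                  sigma2_e, trace)


class MixedForestResults:
    """Fitted mixed-effects forest.

    Attributes
    ----------
    forest : sklearn.ensemble.RandomForestRegressor
        The fixed-effect ensemble (fitted on intercept-adjusted outcome).
    random_effects : pandas.Series
        Estimated intercept per training country.
    sigma2_b, sigma2_e : float
        Country-intercept and residual variance components.
    em_trace : list of dict
        Per-iteration variance components and intercept movement.
    """

    def __init__(self, model, forest, random_effects, sigma2_b, sigma2_e,
                 em_trace):
        self.model = model
        self.forest = forest
        self.random_effects = random_effects
        self.sigma2_b = float(sigma2_b)
        self.sigma2_e = float(sigma2_e)
        self.em_trace = em_trace
        self.exog_names = list(model.exog_names)

    # -- prediction --------------------------------------------------------

    def _coerce(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if list(X.columns) != self.exog_names:
                raise ValueError(
                    "exog columns do not match training order; expected "
                    f"{self.exog_names}, got {list(X.columns)}")
            return X.to_numpy(dtype=float)
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(self.exog_names):
            raise ValueError(f"exog must have {len(self.exog_names)} "
                             f"columns, got shape {arr.shape}")
        return arr

    def predict(self, X, groups=None, include_random: bool = True):
        """Predict on the transformed scale.

        Adds a country's intercept when ``include_random`` and the country
        was seen in training; unknown or omitted countries get intercept 0
        (the random-effect population mean).
        """
        arr = self._coerce(X)
        pred = self.forest.predict(arr)
        if include_random and groups is not None:
            offsets = (pd.Series(np.asarray(groups))
                       .map(self.random_effects).fillna(0.0).to_numpy())
            pred = pred + offsets
        return pred

    @property
    def fittedvalues(self):
        return self.predict(self.model._X, self.model._groups)

    # -- diagnostics -------------------------------------------------------

    def feature_importances(self) -> pd.Series:
        """Impurity-decrease (Gini) importance per feature, summing to 1."""
        return pd.Series(self.forest.feature_importances_,
                         index=self.exog_names, name="gini_importance")

    def proximity(self, X=None) -> np.ndarray:
        """Pairwise fraction of trees in which two farms share a terminal
        node, over all trees and all observations (symmetric, unit
        diagonal, entries in [0, 1])."""
        arr = self.model._X if X is None else self._coerce(X)
        leaves = self.forest.apply(arr)  # (n, T)
        n, T = leaves.shape
        prox = np.zeros((n, n))
        for t in range(T):
            col = leaves[:, t]
            prox += (col[:, None] == col[None, :])
        return prox / T

    def summary(self) -> str:
        lines = ["Mixed-effects random forest results",
                 "=" * 51,
                 f"No. observations: {len(self.model._y):>6}    "
                 f"No. groups: {len(self.random_effects):>4}",
                 f"Trees: {self.model.config.n_trees:>6}    "
                 f"mtry: {self.model.config.resolve_mtry(len(self.exog_names))}",
                 f"sigma2 (country): {self.sigma2_b:10.4f}",
                 f"sigma2 (residual): {self.sigma2_e:9.4f}",
                 f"EM iterations: {len(self.em_trace)}",
                 "-" * 51,
                 "Top features by Gini importance:"]
        imp = self.feature_importances().sort_values(ascending=False)
        for name, val in imp.head(10).items():
            lines.append(f"  {name:<28}{val:8.4f}")
        return "\n".join(lines)

    def save(self, path):
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "MixedForestResults":
        return joblib.load(path)


# -- functional wrappers ---------------------------------------------------

def fit_mixrf(X, y, groups, config: MixRFConfig | None = None,
              **kwargs) -> MixedForestResults:
    """Fit a mixed-effects forest (functional wrapper over MixedForest)."""
    return MixedForest(y, X, groups, config=config, **kwargs).fit()


def predict(results: MixedForestResults, X, groups=None,
            include_random: bool = True):
    return results.predict(X, groups=groups, include_random=include_random)


def gini_importance(results: MixedForestResults) -> pd.Series:
    return results.feature_importances()


def proximity(results: MixedForestResults, X=None) -> np.ndarray:
    return results.proximity(X)
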