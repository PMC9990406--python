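"""Outcome/covariate transformation, feature filtering and encoding.

The farm table is a pandas DataFrame with one row per farm:

* ``country`` — categorical group identifier,
* ``broilers_per_round``, ``rounds_per_year``, ``n_workers`` — production
  ("null model") covariates,
* binary biosecurity answers in {0, 1, NaN} (columns named ``q_###`` by the
  synthetic generator, but any column list can be supplied),
* ``tiddd`` — antimicrobial usage as treatment incidence per 1000
  animal-days (TIDDDvet; TIDDDvet/10 = percent of life under treatment).

The outcome is analysed on a started-log scale, ``z = ln(ti + 1)``, which is
finite at zero and tames the handful of high outliers typical of farm-level
usage data.  Binary answers keep a third "missing" level (coded
:data:`MISSING_LEVEL`) so tree models can route residual missingness, and
the size covariates are natural-log transformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Integer code used for the third, "missing" level of a binary answer.
MISSING_LEVEL = 2

#: Covariate columns of the null model (farm size / productivity proxies).
COVARIATES = ("broilers_per_round", "rounds_per_year", "n_workers")


def transform_amu(ti):
    """Started-log transform of TIDDDvet: ``ln(ti + 1)``.

    Strictly increasing and finite at 0, so zero-usage farms stay in the
    analysis.  Accepts scalars or arrays; negative input raises.
    """
    arr = np.asarray(ti, dtype=float)
    if np.any(arr < 0):
        raise ValueError("TIDDDvet must be non-negative, got minimum "
                         f"{np.min(arr)!r}")
    out = np.log1p(arr)
    return float(out) if np.isscalar(ti) or arr.ndim == 0 else out


def inverse_transform_amu(z):
    """Inverse of :func:`transform_amu`: ``exp(z) - 1``.

    Values of ``z`` below 0 (predictions below the transform of zero usage)
    are clamped to a TIDDDvet of 0 with a logged warning.
    """
    arr = np.asarray(z, dtype=float)
    if np.any(arr < 0):
        logger.warning("clamping %d transformed prediction(s) below 0 to "
                       "TIDDDvet 0", int(np.sum(arr < 0)))
    out = np.clip(np.expm1(arr), 0.0, None)
    return float(out) if np.isscalar(z) or arr.ndim == 0 else out


@dataclass
class PreprocessReport:
    """Which features were excluded (and why) and which keep a missing level."""

    excluded_missing: list = field(default_factory=list)
    excluded_lowvar: list = field(default_factory=list)
    indicator_features: list = field(default_factory=list)

    def to_dict(self):
        return {
            "excluded_missing": list(self.excluded_missing),
            "excluded_lowvar": list(self.excluded_lowvar),
            "indicator_features": list(self.indicator_features),
        }


def feature_columns(table: pd.DataFrame) -> list:
    """Binary-answer columns of a farm table (``q_`` prefix convention)."""
    return [c for c in table.columns if c.startswith("q_")]


def filter_features(table: pd.DataFrame, features=None,
                    missing_max: float = 0.10,
                    variation_min: float = 0.15):
    """Drop survey answers with too much missingness or too little variation.

    A feature is excluded when its missing fraction exceeds ``missing_max``,
    or otherwise when its minority-level share among non-missing values is
    below ``variation_min``.

    Returns ``(retained, report)`` where ``report`` is a
    :class:`PreprocessReport`.
    """
    if len(table) == 0:
        raise ValueError("cannot filter features of an empty farm table")
    if features is None:
        features = feature_columns(table)

    report = PreprocessReport()
    retained = []
    n = len(table)
    for feat in features:
        col = table[feat]
        n_missing = int(col.isna().sum()) + int((col == MISSING_LEVEL).sum())
        if n_missing / n > missing_max:
            report.excluded_missing.append(feat)
            continue
        observed = col[col.notna() & (col != MISSING_LEVEL)]
        if len(observed) == 0:
            report.excluded_missing.append(feat)
            continue
        share_one = float((observed == 1).mean())
        minority = min(share_one, 1.0 - share_one)
        if minority < variation_min:
            report.excluded_lowvar.append(feat)
            continue
        retained.append(feat)
        if n_missing > 0:
            report.indicator_features.append(feat)
    return retained, report


def encode(table: pd.DataFrame, retained) -> pd.DataFrame:
    """Build the model matrix for the mixed-effects forest.

    Columns, in order: ``log_broilers_per_round``, ``rounds_per_year``,
    ``log_n_workers``, then the retained binary answers coded 0/1 with
    remaining missing cells set to the third level :data:`MISSING_LEVEL`.
    """
    for cov in ("broilers_per_round", "n_workers"):
        vals = table[cov].to_numpy(dtype=float)
        if np.any(vals <= 0):
            raise ValueError(f"{cov} must be strictly positive for the log "
                             "transform")
    X = pd.DataFrame(index=table.index)
    X["log_broilers_per_round"] = np.log(table["broilers_per_round"]
                                         .to_numpy(dtype=float))
    X["rounds_per_year"] = table["rounds_per_year"].to_numpy(dtype=float)
    X["log_n_workers"] = np.log(table["n_workers"].to_numpy(dtype=float))
    for feat in retained:
        col = table[feat].to_numpy(dtype=float)
        col = np.where(np.isnan(col), float(MISSING_LEVEL), col)
        X[feat] = col
    if X.isna().any().any():
        raise AssertionError("encoded model matrix contains undefined values")
    return X


def preprocess(table: pd.DataFrame, missing_max: float = 0.10,
               variation_min: float = 0.15):
    """Full preprocessing: filter, encode, transform the outcome.

    Returns ``(X, y, groups, retained, report)`` with ``y`` on the
    transformed (started-log) scale and ``groups`` the country labels.
    """
    retained, report = filter_features(table, missing_max=missing_max,
                                       variation_min=variation_min)
    X = encode(table, retained)
    y = transform_amu(table["tiddd"].to_numpy(dtype=float))
    groups = table["country"].to_numpy()
    return X, y, groups, retained, report


def tiddd_to_percent_life(ti: float) -> float:
    """Percent of a broiler's life under treatment: TIDDDvet / 10."""
    if ti < 0:
        raise ValueError("TIDDDvet must be non-negative")
    return ti / 10.0

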