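"""Synthetic farm-table generator with planted ground truth.

Emulates a cross-sectional multi-country broiler study: ~20 farms per
country in 9 countries, ~50 mostly binary biosecurity answers, farm-size
covariates, a country-level random intercept, and total antimicrobial usage
recorded as TIDDDvet.  The outcome is built additively on the transformed
(started-log) scale::

    z = intercept + sum_j beta_j * x_j + interactions
        + gamma' * (centred covariates) + b_country + eps

then back-transformed to TIDDDvet and floored at 0; a configurable fraction
of farms is overwritten with exactly 0 to mimic zero-usage farms, and
designated answers can be masked missing at random.

Binary answers are drawn independently (no between-measure correlation
structure is modelled), so every planted effect is exactly recoverable in
the noise-free limit — the point of the generator is parameter-recovery
testing, not realism of the survey's dependence structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Median broilers per production round used as the log-normal centre.
_BROILERS_MEDIAN = 34_550.0
#: Typical number of workers (log-normal centre).
_WORKERS_MEDIAN = 2.0


@dataclass
class SyntheticConfig:
    """Parameters of the generator; defaults give a neutral 180-farm study.

    ``true_effects`` maps feature name (``q_001`` ...) to the planted effect
    on the transformed-AMU scale for applying the measure (1 vs 0); features
    not listed have effect 0.  ``interaction_terms`` is a list of
    ``(feature_i, feature_j, effect)`` products.  ``covariate_effects`` are
    the slopes for (log broilers/round, rounds/year, log workers), applied
    to centred covariates so the intercept stays interpretable.
    """

    n_countries: int = 9
    farms_per_country: int = 20
    n_features: int = 53
    feature_prevalences: dict | None = None
    true_effects: dict = field(default_factory=dict)
    interaction_terms: list = field(default_factory=list)
    covariate_effects: tuple = (-0.3, -0.15, -0.2)
    intercept: float = 4.0
    sigma_country: float = 0.5
    sigma_noise: float = 0.5
    zero_inflation: float = 0.03
    missing_rate: float = 0.0
    missing_features: list | None = None
    farms_per_country_override: dict | None = None
    seed: int = 0

    def feature_names(self) -> list:
        return [f"q_{i + 1:03d}" for i in range(self.n_features)]

    def validate(self):
        if self.n_countries < 1 or self.farms_per_country < 1:
            raise ValueError("n_countries and farms_per_country must be >= 1")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        for name, val in (("sigma_country", self.sigma_country),
                          ("sigma_noise", self.sigma_noise)):
            if val < 0:
                raise ValueError(f"{name} must be >= 0, got {val}")
        for name, val in (("zero_inflation", self.zero_inflation),
                          ("missing_rate", self.missing_rate)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        names = set(self.feature_names())
        for feat in self.true_effects:
            if feat not in names:
                raise ValueError(f"true_effects refers to unknown feature "
                                 f"{feat!r}")
        for fi, fj, _ in self.interaction_terms:
            if fi not in names or fj not in names:
                raise ValueError("interaction_terms refer to unknown "
                                 f"features ({fi!r}, {fj!r})")
        if self.feature_prevalences is not None:
            for feat, p in self.feature_prevalences.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"prevalence of {feat!r} outside [0, 1]")

    def prevalences(self) -> dict:
        """Per-feature Bernoulli probabilities (defaults drawn u[0.2, 0.8]
        from the config seed, so they are stable for a given config)."""
        names = self.feature_names()
        rng = np.random.default_rng(self.seed + 101)
        base = dict(zip(names, rng.uniform(0.2, 0.8, size=len(names))))
        if self.feature_prevalences:
            base.update(self.feature_prevalences)
        return base


def ground_truth(config: SyntheticConfig) -> dict:
    """Planted main effect per feature (0 for unlisted features)."""
    config.validate()
    return {f: float(config.true_effects.get(f, 0.0))
            for f in config.feature_names()}


def country_intercepts(config: SyntheticConfig) -> dict:
    """The planted random intercepts, reproducible from the config seed."""
    config.validate()
    rng = np.random.default_rng(config.seed + 202)
    countries = [f"C{i + 1:02d}" for i in range(config.n_countries)]
    b = rng.normal(0.0, config.sigma_country, size=config.n_countries)
    return dict(zip(countries, b.tolist()))


def generate_farms(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate a farm table.

    Deterministic given (config, seed): identical configs give byte-identical
    tables.  Raises ``ValueError`` on an invalid config.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = config.feature_names()
    prev = config.prevalences()
    intercepts = country_intercepts(config)

    rows_per_country = []
    for i in range(config.n_countries):
        c = f"C{i + 1:02d}"
        n_c = config.farms_per_country
        if config.farms_per_country_override:
            n_c = int(config.farms_per_country_override.get(c, n_c))
        rows_per_country.append((c, n_c))
    n = sum(nc for _, nc in rows_per_country)

    country = np.concatenate([[c] * nc for c, nc in rows_per_country])
    b = np.concatenate([[intercepts[c]] * nc for c, nc in rows_per_country])

    broilers = np.exp(rng.normal(np.log(_BROILERS_MEDIAN), 0.5, size=n))
    broilers = np.round(broilers / 50.0) * 50.0  # survey-style rounding
    rounds = rng.integers(5, 9, size=n).astype(float)
    workers = np.maximum(
        1, np.round(np.exp(rng.normal(np.log(_WORKERS_MEDIAN), 0.5, size=n))))

    feats = {f: (rng.random(n) < prev[f]).astype(float) for f in names}

    z = np.full(n, config.intercept, dtype=float)
    for f, beta in config.true_effects.items():
        z += beta * feats[f]
    for fi, fj, beta in config.interaction_terms:
        z += beta * feats[fi] * feats[fj]
    g1, g2, g3 = config.covariate_effects
    z += g1 * (np.log(broilers) - np.log(_BROILERS_MEDIAN))
    z += g2 * (rounds - 6.5)
    z += g3 * (np.log(workers) - np.log(_WORKERS_MEDIAN))
    z += b
    z += rng.normal(0.0, config.sigma_noise, size=n)

    tiddd = np.clip(np.expm1(z), 0.0, None)
    zero_mask = rng.random(n) < config.zero_inflation
    tiddd[zero_mask] = 0.0

    table = pd.DataFrame({
        "farm_id": [f"F{i + 1:03d}" for i in range(n)],
        "country": country,
        "broilers_per_round": broilers,
        "rounds_per_year": rounds,
        "n_workers": workers,
    })
    for f in names:
        table[f] = feats[f]
    table["tiddd"] = tiddd

    if config.missing_rate > 0:
        targets = config.missing_features
        if targets is None:
            targets = names[:max(1, config.n_features // 10)]
        for f in targets:
            mask = rng.random(n) < config.missing_rate
            table.loc[mask, f] = np.nan
    return table


def recovery_config(seed: int = 0, n_features: int = 30,
                    effect_size: float = 0.8,
                    sigma_noise: float = 0.25) -> SyntheticConfig:
    """Study conditions for parameter-recovery experiments.

    180 farms in 9 countries, unit country-intercept SD, three planted main
    effects of magnitude ``effect_size`` (two harmful when applied, one
    protective) among ``n_features`` answers, low residual noise, no zero
    inflation or missingness.
    """
    return SyntheticConfig(
        n_countries=9, farms_per_country=20, n_features=n_features,
        true_effects={"q_001": effect_size, "q_002": -effect_size,
                      "q_003": effect_size},
        # planted measures at 50% prevalence so they are maximally
        # informative and never trip the low-variation filter
        feature_prevalences={"q_001": 0.5, "q_002": 0.5, "q_003": 0.5},
        sigma_country=1.0, sigma_noise=sigma_noise,
        zero_inflation=0.0, missing_rate=0.0, seed=seed)
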