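"""Scenario enumeration and farm-specific usage-reduction plans.

Given a farm's screened weaknesses (candidate interventions), every
nonempty combination of them defines a scenario: the corresponding answers
are flipped on the farm's row and predicted usage is recomputed.  Because
forest effect estimates carry Monte-Carlo uncertainty, the whole model is
refitted ``n_runs`` (default 10) times with distinct seeds; only features
whose partial-dependence effect keeps the same sign in every run enter
scenarios, and each scenario's prediction is the mean over the runs,
back-transformed to TIDDDvet units before averaging.

Scenarios predicting below the farm's baseline prediction are "kept"; ids
are assigned in descending predicted-usage order, so the deepest reduction
gets the largest index, and the report lists kept scenarios best-first.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .effects import partial_effect
from .mixrf import MixRFConfig, fit_mixrf
from .preprocess import inverse_transform_amu

logger = logging.getLogger(__name__)

MAX_CANDIDATES = 15


@dataclass
class Scenario:
    id: str
    flipped_features: frozenset
    predicted_ti: float = np.nan
    pct_change: float = np.nan
    kept: bool = False
    yearly_cost: float = np.nan
    cost_per_ti: float = np.nan


@dataclass
class PlanReport:
    farm_id: object
    original_ti: float
    baseline_prediction_ti: float
    strengths: list = field(default_factory=list)
    weaknesses: list = field(default_factory=list)
    scenarios: list = field(default_factory=list)

    def to_dict(self):
        return {
            "farm_id": self.farm_id,
            "original_ti": self.original_ti,
            "baseline_prediction_ti": self.baseline_prediction_ti,
            "strengths": list(self.strengths),
            "weaknesses": list(self.weaknesses),
            "scenarios": [{
                "id": s.id,
                "flipped_features": sorted(s.flipped_features),
                "predicted_ti": s.predicted_ti,
                "pct_change": s.pct_change,
                "kept": s.kept,
                "yearly_cost": s.yearly_cost,
                "cost_per_ti": s.cost_per_ti,
            } for s in self.scenarios],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    def to_table(self) -> str:
        """Human-readable plan: one row per kept scenario, best first."""
        header = (f"{'scenario':<12}{'flipped measures':<40}"
                  f"{'TIDDDvet':>10}{'% change':>10}{'EUR/yr':>12}"
                  f"{'EUR/TIDDDvet':>14}")
        lines = [f"Farm {self.farm_id}: original {self.original_ti:.2f} "
                 f"TIDDDvet, baseline prediction "
                 f"{self.baseline_prediction_ti:.2f}",
                 header, "-" * len(header)]
        for s in self.scenarios:
            if not s.kept:
                continue
            feats = ",".join(sorted(s.flipped_features))
            cost = "" if np.isnan(s.yearly_cost) else f"{s.yearly_cost:.2f}"
            cpt = "" if np.isnan(s.cost_per_ti) else f"{s.cost_per_ti:.2f}"
            lines.append(f"{s.id:<12}{feats:<40}{s.predicted_ti:>10.2f}"
                         f"{s.pct_change:>10.1f}{cost:>12}{cpt:>14}")
        return "\n".join(lines)


def enumerate_scenarios(candidates) -> list:
    """All 2^k - 1 nonempty subsets of the candidate interventions."""
    candidates = sorted(set(candidates))
    k = len(candidates)
    if k == 0:
        logger.info("no candidate interventions; empty plan")
        return []
    if k > MAX_CANDIDATES:
        raise ValueError(
            f"{k} candidates would enumerate {2 ** k - 1} scenarios; "
            f"pre-filter to at most {MAX_CANDIDATES}")
    subsets = []
    for r in range(1, k + 1):
        for combo in combinations(candidates, r):
            subsets.append(Scenario(id="", flipped_features=frozenset(combo)))
    return subsets


def percent_change(baseline_ti: float, scenario_ti: float) -> float:
    """Signed percent change of a scenario prediction vs baseline,
    rounded to 1 d.p."""
    if baseline_ti <= 0:
        raise ValueError("percent change undefined for baseline TIDDDvet "
                         f"{baseline_ti}")
    return round((scenario_ti - baseline_ti) / baseline_ti * 100.0, 1)


def run_consistency(X: pd.DataFrame, y, groups, features,
                    mixrf_config: MixRFConfig | None = None,
                    n_runs: int = 10):
    """Refit the model ``n_runs`` times with distinct seeds and count
    per-feature effect-sign agreement.

    Returns ``(models, counts)`` where ``counts[f]`` is the size of the
    larger sign camp over the runs; a feature is fully consistent when
    ``counts[f] == n_runs``.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2 to assess consistency")
    if mixrf_config is None:
        mixrf_config = MixRFConfig()
    models, signs = [], {f: [] for f in features}
    for r in range(n_runs):
        cfg = MixRFConfig(**{**mixrf_config.__dict__,
                             "seed": mixrf_config.seed + r})
        res = fit_mixrf(X, y, groups, config=cfg)
        models.append(res)
        for f in features:
            signs[f].append(np.sign(partial_effect(res, X, f)))
    counts = {}
    for f, s in signs.items():
        s = np.asarray(s)
        counts[f] = int(max((s > 0).sum(), (s < 0).sum()))
    return models, counts


def evaluate(farm_row: pd.Series, scenarios: list, models: list,
             country=None, original_ti: float = np.nan,
             farm_id=None) -> PlanReport:
    """Predict every scenario with every run's model and assemble the plan.

    ``farm_row`` is the farm's encoded model-matrix row.  For each
    scenario the listed answers are flipped (x -> 1 - x), each model
    predicts on the transformed scale, predictions are back-transformed to
    TIDDDvet and averaged over models.  Baseline uses the unmodified row.
    Kept scenarios predict strictly below baseline; ids are assigned in
    descending predicted order (deepest cut gets the largest index) and
    the report is ordered best-first.
    """
    exog_names = models[0].exog_names
    if list(farm_row.index) != exog_names:
        raise ValueError("farm row columns do not match the model's "
                         "training order")
    groups_arg = None if country is None else np.asarray([country])

    def mean_ti(row: pd.Series) -> float:
        frame = row.to_frame().T
        preds = [inverse_transform_amu(float(
            m.predict(frame, groups=groups_arg)[0])) for m in models]
        return float(np.mean(preds))

    baseline = mean_ti(farm_row)
    for s in scenarios:
        row = farm_row.copy()
        for f in s.flipped_features:
            row[f] = 1.0 - row[f]
        s.predicted_ti = mean_ti(row)
        s.kept = s.predicted_ti < baseline
        s.pct_change = percent_change(baseline, s.predicted_ti) \
            if baseline > 0 else np.nan
    ordered = sorted(scenarios, key=lambda s: -s.predicted_ti)
    for i, s in enumerate(ordered, start=1):
        s.id = f"Scenario_{i}"
    report = PlanReport(farm_id=farm_id, original_ti=float(original_ti),
                        baseline_prediction_ti=baseline,
                        scenarios=sorted(scenarios,
                                         key=lambda s: s.predicted_ti))
    return report
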