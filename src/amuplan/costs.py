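"""Yearly intervention costs and cost-effectiveness per TIDDDvet unit.

Each biosecurity measure has a :class:`CostItem`: a one-off implementation
cost depreciated linearly over its lifetime, a yearly operational cost,
and an optional scaling term tied to the farm's production profile
(per animal, per round, or per stable).  A scenario's yearly cost is the
sum over its flipped measures; cost-effectiveness divides that by the
predicted TIDDDvet change, so usage *reductions* give negative
euros-per-TIDDDvet (cost per unit of reduction).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import yaml

logger = logging.getLogger(__name__)

SCALINGS = ("fixed", "per_animal", "per_round", "per_stable")

#: Stable count assumed when a farm does not report one.
DEFAULT_N_STABLES = 2


@dataclass
class CostItem:
    feature: str
    implementation_cost: float = 0.0
    lifetime_years: float = 1.0
    operational_cost: float = 0.0
    scaling: str = "fixed"
    scale_rate: float = 0.0

    def validate(self):
        if self.lifetime_years < 1:
            raise ValueError(f"lifetime_years must be >= 1 for "
                             f"{self.feature!r}")
        if self.scaling not in SCALINGS:
            raise ValueError(f"unknown scaling {self.scaling!r}; expected "
                             f"one of {SCALINGS}")


def load_cost_table(path=None) -> dict:
    """Costs YAML -> {feature: CostItem}.

    Without a path, the packaged illustrative table is loaded (synthetic
    price points; real deployments supply their own YAML).
    """
    if path is None:
        text = (resources.files("amuplan.data") / "example_costs.yaml")\
            .read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    table = {}
    for feat, fields in raw.items():
        item = CostItem(feature=feat, **fields)
        item.validate()
        table[feat] = item
    return table


def yearly_cost(item: CostItem, farm) -> float:
    """Yearly cost of one measure on one farm.

    Depreciation (implementation / lifetime) + operational + scaling term.
    ``farm`` is a mapping or Series with the production fields required by
    the item's scaling rule; a missing field raises.
    """
    item.validate()
    total = item.implementation_cost / item.lifetime_years \
        + item.operational_cost
    if item.scaling == "fixed":
        return total

    def need(key):
        try:
            val = farm[key]
        except (KeyError, IndexError, TypeError):
            val = None
        if val is None:
            if key == "n_stables":
                logger.info("n_stables unknown for %r; assuming %d",
                            item.feature, DEFAULT_N_STABLES)
                return DEFAULT_N_STABLES
            raise ValueError(f"farm field {key!r} required by scaling "
                             f"{item.scaling!r} of {item.feature!r}")
        return float(val)

    if item.scaling == "per_animal":
        total += item.scale_rate * need("broilers_per_round") \
            * need("rounds_per_year")
    elif item.scaling == "per_round":
        total += item.scale_rate * need("rounds_per_year")
    elif item.scaling == "per_stable":
        total += item.scale_rate * need("n_stables")
    return total


def scenario_cost(flipped_features, cost_table: dict, farm) -> float:
    """Sum of yearly costs over a scenario's flipped measures.

    Measures without a cost item are costed 0 with a warning.
    """
    total = 0.0
    for feat in flipped_features:
        if feat not in cost_table:
            warnings.warn(f"no cost item for {feat!r}; costed 0",
                          RuntimeWarning, stacklevel=2)
            continue
        total += yearly_cost(cost_table[feat], farm)
    return total


def cost_effectiveness(yearly: float, baseline_ti: float,
                       scenario_ti: float) -> float:
    """Euros per unit of TIDDDvet change: cost / (scenario - baseline).

    Negative for reductions.  Undefined (raises) when the predictions are
    equal.
    """
    diff = scenario_ti - baseline_ti
    if diff == 0:
        raise ZeroDivisionError("cost-effectiveness undefined: scenario "
                                "and baseline predictions are equal")
    return yearly / diff


def attach_costs(report, cost_table: dict, farm) -> None:
    """Fill yearly_cost / cost_per_ti on every scenario of a plan report."""
    for s in report.scenarios:
        s.yearly_cost = scenario_cost(s.flipped_features, cost_table, farm)
        diff = s.predicted_ti - report.baseline_prediction_ti
        s.cost_per_ti = (s.yearly_cost / diff) if diff != 0 else float("nan")
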