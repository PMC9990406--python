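"""End-to-end orchestration: simulate/load -> preprocess -> RFE -> final
model -> clustering/prototypes -> effects -> per-farm plans with costs.

A run is fully described by a :class:`RunConfig`; every artefact written
carries the config hash, and a rerun with an identical config reproduces
the artefacts bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, costs, effects, planner, synthetic
from .mixrf import MixRFConfig
from .preprocess import preprocess as preprocess_table
from .rfe import RFEConfig, run_rfe

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    farm_csv: str | None = None        # None -> simulate
    costs_yaml: str | None = None      # None -> packaged example table
    expectations_yaml: str | None = None
    expectations: dict = field(default_factory=dict)  # inline override
    output_dir: str = "amuplan_run"
    seed: int = 0
    n_consistency_runs: int = 10
    plan_farms: list = field(default_factory=list)  # [] -> first farm
    run_planner: bool = True
    run_clustering: bool = True
    synthetic: dict = field(default_factory=dict)
    mixrf: dict = field(default_factory=dict)
    rfe: dict = field(default_factory=dict)

    def to_dict(self):
        return asdict(self)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location aside)."""
        d = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            return RunConfig(**(yaml.safe_load(fh) or {}))


def _dump_json(obj, path: Path, config_hash: str):
    payload = {"config_hash": config_hash, "result": obj}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=_jsonable))
    return path


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (set, frozenset)):
        return sorted(x)
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def run_pipeline(config: RunConfig) -> Path:
    """Execute every enabled stage and write artefacts to the output dir.

    Returns the artefact directory.  Any stage failure aborts with a
    stage-scoped error message.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    timings = {}

    def stage(name):
        logger.info("stage %s ...", name)
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    try:
        s = stage("data")
        if config.farm_csv:
            table = pd.read_csv(config.farm_csv)
        else:
            scfg = synthetic.SyntheticConfig(
                **{"seed": config.seed, **config.synthetic})
            table = synthetic.generate_farms(scfg)
        table.to_csv(out / "farms.csv", index=False)
        done(s)

        s = stage("preprocess")
        X, y, groups, retained, report = preprocess_table(table)
        _dump_json(report.to_dict(), out / "preprocess_report.json", h)
        done(s)

        s = stage("rfe")
        rfe_cfg = RFEConfig(**{"seed": config.seed, **config.rfe})
        mix_cfg = MixRFConfig(**{"seed": config.seed, **config.mixrf})
        rfe_res = run_rfe(X, y, groups, config=rfe_cfg,
                          mixrf_config=mix_cfg)
        _dump_json(rfe_res.to_dict(), out / "rfe_result.json", h)
        final_X = X[rfe_res.final_features]
        done(s)

        s = stage("fit")
        models, consistency = planner.run_consistency(
            final_X, y, groups,
            features=[f for f in rfe_res.final_features
                      if set(final_X[f].dropna().unique()) <= {0.0, 1.0}],
            mixrf_config=mix_cfg, n_runs=config.n_consistency_runs)
        final = models[0]
        final.save(out / "model.joblib")
        (out / "model_summary.txt").write_text(final.summary() + "\n")
        done(s)

        s = stage("effects")
        X_imp = effects.impute_missing_levels(final_X, seed=config.seed)
        eff = {f: float(np.mean([effects.partial_effect(m, X_imp, f)
                                 for m in models]))
               for f in consistency}
        importance = final.feature_importances()
        eff_table = pd.DataFrame({
            "feature": list(eff),
            "gini_importance": [float(importance[f]) for f in eff],
            "effect": [eff[f] for f in eff],
            "sign_consistency": [consistency[f] for f in eff],
        }).sort_values("feature")
        eff_table.to_csv(out / "effects.csv", index=False)
        done(s)

        if config.run_clustering:
            s = stage("clustering")
            prox = final.proximity()
            pd.DataFrame(prox).to_csv(out / "proximity.csv", index=False)
            coords = clustering.embed(prox, dims=3)
            cmodel = clustering.cluster(coords, seed=config.seed)
            labels = clustering.label_users(
                y, final.predict(final_X, groups), table["farm_id"])
            protos = clustering.prototypes(table, cmodel.assignments, labels)
            clustering.prototypes_frame(protos).to_csv(
                out / "prototypes.csv")
            pd.DataFrame({
                "farm_id": table["farm_id"],
                "cluster": cmodel.assignments,
                "real_label": [l.real_label for l in labels],
                "predicted_label": [l.predicted_label for l in labels],
            }).to_csv(out / "clusters.csv", index=False)
            done(s)

        if config.run_planner:
            s = stage("planner")
            expectations = (dict(config.expectations) if config.expectations
                            else effects.load_expectations(
                                config.expectations_yaml))
            cost_table = costs.load_cost_table(config.costs_yaml)
            consistent = [f for f, c in consistency.items()
                          if c == config.n_consistency_runs]
            plan_dir = out / "plans"
            plan_dir.mkdir(exist_ok=True)
            farm_ids = config.plan_farms or [table["farm_id"].iloc[0]]
            for fid in farm_ids:
                row = table.loc[table["farm_id"] == fid]
                if len(row) != 1:
                    raise ValueError(f"farm {fid!r} not found (or "
                                     "duplicated) in the farm table")
                farm_x = X_imp.loc[row.index[0]]
                values = {f: int(farm_x[f]) for f in consistent}
                sw = effects.classify(values, eff)
                candidates = effects.filter_by_expectation(
                    sw, eff, expectations)
                report_ = planner.evaluate(
                    farm_x, planner.enumerate_scenarios(candidates),
                    models, country=row["country"].iloc[0],
                    original_ti=float(row["tiddd"].iloc[0]), farm_id=fid)
                report_.strengths = [w.feature for w in sw
                                     if w.label == "strength"]
                report_.weaknesses = [w.feature for w in sw
                                      if w.label == "weakness"]
                costs.attach_costs(report_, cost_table, row.iloc[0])
                (plan_dir / f"{fid}.json").write_text(report_.to_json())
            done(s)

        (out / "run_config.yaml").write_text(
            yaml.safe_dump({"config_hash": h, **config.to_dict()}))
        _dump_json(timings, out / "timings.json", h)
        manifest = sorted(str(p.relative_to(out))
                          for p in out.rglob("*") if p.is_file())
        _dump_json({"files": manifest}, out / "MANIFEST.json", h)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {s!r} failed: {exc}") from exc
    logger.info("pipeline complete: %s", out)
    return out
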