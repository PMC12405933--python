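"""End-to-end orchestration: config, artifacts, manifest.

``run_pipeline`` drives the published analysis flow on a cohort CSV (or a
freshly simulated one): recode → impute → discretize → bootstrap-consensus
structure learning under expert constraints → CPT fitting → counterfactuals →
validation.  Every artifact lands in the output directory and the manifest
records the config hash and each stage's derived seed, so a rerun with the
same config reproduces every file bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocessing as prep
from .bayesnet import counterfactual_compare, fit_cpts
from .cohort_io import read_cohort_csv
from .data import DiscreteData
from .ensemble import (ExpertConstraints, apply_expert_constraints,
                       averaged_network, bootstrap_strengths)
from .graphs import NetworkStructure, pdag_to_dag
from .synthetic import inject_missingness, make_ground_truth_network, sample_cohort
from .validation import (OUTCOME, PREDICTORS, PipelineSettings, cross_validate,
                         make_folds, train_test_split_report)

__all__ = ["PipelineConfig", "run_pipeline", "export_graph", "load_config"]


@dataclass
class PipelineConfig:
    cohort_csv: str | None = None        # input table; None -> simulate
    preset: str = "core9"
    n_simulate: int = 20000
    predictors: list[str] = field(default_factory=lambda: list(PREDICTORS))
    algorithms: tuple = ("hc", "tabu", "pc_stable", "gs", "mmpc")
    B: int = 1000                        # published bootstrap count
    threshold: float = 0.75              # published arc-selection threshold
    m_fraction: float = 1.0
    whitelist: list = field(default_factory=list)
    blacklist: list = field(default_factory=list)
    rebalance_training_folds: bool = False
    validation_scheme: str = "kfold"     # "kfold" | "loco"
    k_folds: int = 10
    split_fraction: float = 0.70
    counterfactual_node: str = "crs"
    counterfactual_levels: tuple = ("None", "CRSwoNP", "CRSwNP")
    smoothing_alpha: float = 1.0
    seed: int = 0
    out_dir: str = "results/pipeline"

    def validate(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must lie in (0, 1]")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.cohort_csv is not None and not Path(self.cohort_csv).exists():
            raise FileNotFoundError(self.cohort_csv)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    text = Path(path).read_text()
    if str(path).endswith((".yml", ".yaml")):
        import yaml
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ["simulate", "missingness", "impute", "bootstrap", "folds",
             "split", "rebalance"]
    return {n: int(s.generate_state(1)[0] % (2 ** 31))
            for n, s in zip(names, ss.spawn(len(names)))}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the artifact set; returns the manifest."""
    config.validate()
    seeds = _stage_seeds(config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config),
                      "config_hash": config.content_hash(),
                      "stage_seeds": seeds, "stages": []}

    def stage(name, fn):
        t0 = time.time()
        try:
            result = fn()
        except Exception as err:
            raise RuntimeError(
                f"stage:{name} failed ({type(err).__name__}): {err}") from err
        manifest["stages"].append({"stage": name,
                                   "seconds": round(time.time() - t0, 2)})
        return result

    spec = make_ground_truth_network(config.preset)

    def _load():
        if config.cohort_csv:
            return read_cohort_csv(config.cohort_csv)
        coh = sample_cohort(spec, config.n_simulate, seed=seeds["simulate"])
        return inject_missingness(coh, spec, seed=seeds["missingness"])

    cohort = stage("load_or_simulate", _load)
    cohort.to_csv(out / "cohort.csv", index=False)

    def _recode():
        rules = prep.RecodeRules(
            zero_to_missing=tuple(c for c in ("bec", "feno", "ige")
                                  if c in config.predictors),
            bounds={c: b for c, b in prep.RecodeRules().bounds.items()
                    if c in config.predictors})
        return prep.recode_zeros_and_outliers(
            cohort[config.predictors + [OUTCOME, "country", "patient_id"]],
            rules)
    recoded, recode_log = stage("recode", _recode)
    (out / "recode_log.json").write_text(json.dumps(recode_log, indent=1))

    def _impute():
        if not recoded[config.predictors].isna().any().any():
            return recoded
        return prep.impute_iterative_forest(
            recoded, columns=config.predictors,
            seed=seeds["impute"]).completed
    imputed = stage("impute", _impute)
    imputed.to_csv(out / "cohort_imputed.csv", index=False)

    def _discretize():
        dmap = prep.default_clinical_cuts()
        dmap = prep.DiscretizationMap(
            {c: v for c, v in dmap.cuts.items() if c in config.predictors},
            {c: v for c, v in dmap.labels.items() if c in config.predictors},
            dmap.method)
        return prep.apply_discretization(imputed, dmap), dmap
    disc, dmap = stage("discretize", _discretize)
    (out / "discretization.json").write_text(dmap.to_json())
    disc.to_csv(out / "cohort_discrete.csv", index=False)

    constraints = ExpertConstraints(
        whitelist={tuple(a) for a in config.whitelist},
        blacklist={tuple(a) for a in config.blacklist})

    def _learn():
        d = DiscreteData.from_dataframe(disc, config.predictors + [OUTCOME])
        st = bootstrap_strengths(
            d, algorithms=config.algorithms, B=config.B,
            m_fraction=config.m_fraction, constraints=constraints,
            seed=seeds["bootstrap"])
        avg = averaged_network(st, config.threshold)
        final = apply_expert_constraints(avg, constraints)
        dag = pdag_to_dag(final)
        return st, avg, dag
    strengths, avg, dag = stage("learn_structure", _learn)
    strengths.to_dataframe().to_csv(out / "arc_strengths.csv", index=False)
    labels = {(u, v): f"{strengths.adjacency_frequency(u, v):.2f}"
              for (u, v) in avg.arcs}
    labels.update({frozenset(e): f"{strengths.adjacency_frequency(*sorted(e)):.2f}"
                   for e in avg.undirected})
    (out / "averaged_network.dot").write_text(avg.to_dot(labels))
    (out / "averaged_network.json").write_text(json.dumps(
        {"arcs": sorted(avg.arcs),
         "undirected": sorted(map(sorted, avg.undirected))}, indent=1))

    def _fit():
        return fit_cpts(dag, disc[config.predictors + [OUTCOME]].dropna(),
                        config.smoothing_alpha)
    net = stage("fit_cpts", _fit)
    (out / "fitted_network.json").write_text(net.to_json())

    def _counterfactual():
        if config.counterfactual_node not in net.dag.nodes:
            return pd.DataFrame()
        return counterfactual_compare(
            net, config.counterfactual_node, config.counterfactual_levels)
    cf = stage("counterfactual", _counterfactual)
    cf.to_csv(out / "counterfactuals.csv", index=False)

    def _validate():
        settings = PipelineSettings(
            predictors=list(config.predictors),
            rebalance=config.rebalance_training_folds,
            structure="hc", smoothing_alpha=config.smoothing_alpha,
            seed=seeds["folds"])
        plan = make_folds(cohort, config.validation_scheme, config.k_folds,
                          seed=seeds["folds"])
        cv = cross_validate(cohort, settings, plan)
        split = train_test_split_report(cohort, settings,
                                        config.split_fraction,
                                        seed=seeds["split"])
        return cv, split
    cv_report, split_report = stage("validate", _validate)
    (out / "validation_cv.json").write_text(cv_report.to_json())
    (out / "validation_split.json").write_text(split_report.to_json())
    if cv_report.predictions is not None:
        cv_report.predictions.to_csv(out / "fold_predictions.csv", index=False)

    for f in sorted(out.iterdir()):
        if f.name == "manifest.json" or not f.is_file():
            continue
        manifest.setdefault("artifacts", {})[f.name] = hashlib.sha256(
            f.read_bytes()).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def export_graph(network: NetworkStructure, path: str | Path,
                 fmt: str | None = None, edge_labels=None) -> Path:
    """Write a network as DOT, GraphML or a 2-column arc CSV."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".")
    if fmt == "dot":
        path.write_text(network.to_dot(edge_labels))
    elif fmt == "graphml":
        path.write_text(network.to_graphml())
    elif fmt == "csv":
        path.write_text(network.to_arc_csv())
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
    return path
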