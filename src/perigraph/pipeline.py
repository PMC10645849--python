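"""End-to-end orchestration: simulate → graph → embed → score → evaluate.

One :class:`RunConfig` (usually loaded from YAML) drives a full run into an
artifact directory containing the cohort CSV + schema, graph exports, the
embedding matrix, per-patient scores, the results table, and a JSON
manifest from which the run can be reproduced bit-identically.

Seeding: one master seed fans out to per-stage seeds through
``numpy.random.SeedSequence(master).spawn`` with a fixed stage order
(cohort, walks, skip-gram, autoencoder), so stages are independent yet
fully determined by the master seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .cohort import CohortTable, RiskFactorSchema, read_cohort_table
from .embed import SkipGramConfig, WalkConfig
from .evaluate import experiment_grid, run_repeated
from .gae import ScoreConfig, TrainConfig, score_outliers
from .kgraph import build_graph, export_graph, graph_stats
from .simulate import SimulationConfig, generate_cohort, preset_by_name


class ConfigError(ValueError):
    """Invalid run configuration (distinct from runtime stage failures)."""


@dataclass(frozen=True)
class RunConfig:
    out_dir: str = "perigraph-run"
    seed: int = 0
    # cohort source: a preset name, an inline simulation, or a CSV + schema
    preset: str | None = "vptb-nulliparous"
    simulation: SimulationConfig | None = None
    cohort_csv: str | None = None
    schema_yaml: str | None = None
    method: str = "combine-32"
    outcome: str | None = None
    repeats: int = 1
    grid: bool = False
    train: TrainConfig = field(default_factory=TrainConfig)
    walk: WalkConfig = field(default_factory=WalkConfig)
    skipgram: SkipGramConfig = field(default_factory=SkipGramConfig)
    include_outcome: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        try:
            sim = doc.pop("simulation", None)
            kwargs = dict(doc)
            if sim is not None:
                kwargs["simulation"] = SimulationConfig(**sim)
                kwargs.setdefault("preset", None)
            for key, typ in (("train", TrainConfig), ("walk", WalkConfig),
                             ("skipgram", SkipGramConfig)):
                if key in kwargs and isinstance(kwargs[key], dict):
                    kwargs[key] = typ(**kwargs[key])
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    def to_manifest(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v):
                return dataclasses.asdict(v)
            return v
        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}


def _stage_seeds(master: int) -> dict:
    names = ("cohort", "walk", "skipgram", "gae")
    children = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def load_cohort(config: RunConfig, cohort_seed: int) -> CohortTable:
    if config.cohort_csv:
        if not config.schema_yaml:
            raise ConfigError("cohort_csv requires schema_yaml")
        schema = RiskFactorSchema.from_yaml(config.schema_yaml)
        return read_cohort_table(config.cohort_csv, schema)
    if config.simulation is not None:
        return generate_cohort(replace(config.simulation, seed=cohort_seed))
    if config.preset:
        return generate_cohort(preset_by_name(config.preset, seed=cohort_seed))
    raise ConfigError("no cohort source: set preset, simulation, or cohort_csv")


def write_scores_tsv(path, patient_ids, errors) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id\treconstruction_error\n")
        for pid, e in zip(patient_ids, errors):
            fh.write(f"{pid}\t{float(e)!r}\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the artifact directory.

    Any stage failure is re-raised with a ``[stage]`` tag so callers can
    tell configuration errors from runtime ones.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)

    def stage(name, fn):
        try:
            return fn()
        except ConfigError:
            raise
        except Exception as exc:
            raise RuntimeError(f"[{name}] {exc}") from exc

    table = stage("cohort", lambda: load_cohort(config, seeds["cohort"]))
    table.write_csv(out / "cohort.csv")
    table.schema.to_yaml(out / "schema.yaml")
    outcome = config.outcome or table.outcome_names[0]
    if outcome not in table.outcome_names:
        raise ConfigError(f"outcome {outcome!r} not in cohort labels {table.outcome_names}")

    g = stage("graph", lambda: build_graph(table, config.include_outcome))
    export_graph(g, out / "graph", "graphml")
    export_graph(g, out / "graph", "neo4j-import-csv")
    stats = graph_stats(g)

    score_cfg = ScoreConfig(train=config.train, walk=config.walk,
                            skipgram=config.skipgram,
                            include_outcome=config.include_outcome,
                            seed=config.seed)

    results_path = None
    if config.grid:
        df = stage("grid", lambda: experiment_grid(
            table, outcome, score_cfg, repeats=config.repeats,
            base_seed=config.seed))
        results_path = out / "results.csv"
        df.to_csv(results_path, index=False)
        scores = stage("score", lambda: score_outliers(table, config.method, score_cfg))
    elif config.repeats > 1:
        res = stage("evaluate", lambda: run_repeated(
            table, config.method, outcome, score_cfg,
            repeats=config.repeats, base_seed=config.seed))
        results_path = out / "results.csv"
        import pandas as pd
        pd.DataFrame([{
            "method": res.method_tag,
            "auc_roc_mean": res.auc_roc_mean,
            "auc_pr_mean": res.auc_pr_mean,
            **{f"auc_roc_seed{config.seed + i}": v
               for i, v in enumerate(res.auc_roc_per_seed)},
        }]).to_csv(results_path, index=False)
        scores = stage("score", lambda: score_outliers(table, config.method, score_cfg))
    else:
        scores = stage("score", lambda: score_outliers(table, config.method, score_cfg))

    write_scores_tsv(out / "scores.tsv", table.patient_id, scores.errors)

    manifest = {
        "config": config.to_manifest(),
        "stage_seeds": seeds,
        "outcome": outcome,
        "graph_stats": dataclasses.asdict(stats),
        "n_patients": table.n,
        "n_features": table.f,
        "final_loss": scores.loss_history[-1],
        "artifacts": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def rerun_from_manifest(manifest_path, out_dir) -> Path:
    """Reproduce a run from its manifest alone (golden-file reproducibility)."""
    doc = json.loads(Path(manifest_path).read_text())
    cfg_doc = doc["config"]
    cfg_doc["out_dir"] = str(out_dir)
    if cfg_doc.get("simulation"):
        cfg_doc["simulation"] = SimulationConfig(**cfg_doc["simulation"])
    else:
        cfg_doc.pop("simulation", None)
    for key, typ in (("train", TrainConfig), ("walk", WalkConfig),
                     ("skipgram", SkipGramConfig)):
        cfg_doc[key] = typ(**cfg_doc[key])
    return run_pipeline(RunConfig(**cfg_doc))
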