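"""Benchmark orchestration: dataset x algorithm grid over one parent model.

``run_benchmark`` executes the full workflow — load model, flux-consistency
reduction, per-sample GPR mapping, per-algorithm extraction, FBA, Warburg and
hallmark scores, pairwise Jaccard / Bland-Altman agreement, and PCA + random
forest flux-fingerprint analysis — and writes a deterministic set of report
tables.  Running twice with the same configuration and seed produces
byte-identical outputs.

Per-sample failures (an infeasible extraction, say) do not abort the
benchmark; they are recorded in the report and the run continues.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cancer_scores import DEFAULT_ALIASES, read_gene_list, score_cgem
from .clusterability import build_flux_matrix, pca_cluster, rf_importance, subsystem_barcode
from .extraction import ExtractionConfig, extract
from .flux_core import fastcc, fba
from .model_io import load_model, protect_reactions, save_model
from .omics_mapping import preprocess, read_expression_tsv, read_metadata_tsv, map_expression
from .pattern_metrics import disagreement_matrix, jaccard_subsystem
from .synthetic_data import hallmark_gene_list

logger = logging.getLogger("cgemkit.pipeline")

__all__ = ["DatasetSpec", "BenchmarkConfig", "HeterogeneityReport", "run_benchmark"]

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class DatasetSpec:
    """One expression dataset: a gene x column TSV plus column metadata."""

    name: str
    expression_path: str
    metadata_path: str


@dataclass(frozen=True)
class BenchmarkConfig:
    """Declarative configuration of a full benchmark run."""

    model_path: str
    datasets: tuple[DatasetSpec, ...]
    out_dir: str
    algorithms: tuple[str, ...] = ("gimme", "imat", "init", "fastcore")
    hallmark_path: str | None = None
    extraction_params: Mapping[str, object] = field(default_factory=dict)
    analyses: tuple[str, ...] = ("scores", "jaccard", "bland_altman", "pca_rf")
    bland_altman_mode: str = "raw"
    rf_top_k: int = 15
    rf_ntree: int = 500
    max_k: int = 8
    write_models: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "datasets",
            tuple(
                d if isinstance(d, DatasetSpec) else DatasetSpec(**d)
                for d in self.datasets
            ),
        )
        object.__setattr__(self, "algorithms", tuple(self.algorithms))
        object.__setattr__(self, "analyses", tuple(self.analyses))
        object.__setattr__(self, "extraction_params", dict(self.extraction_params))

    def to_json_dict(self) -> dict:
        return {
            "model_path": self.model_path,
            "datasets": [
                {
                    "name": d.name,
                    "expression_path": d.expression_path,
                    "metadata_path": d.metadata_path,
                }
                for d in self.datasets
            ],
            "out_dir": self.out_dir,
            "algorithms": list(self.algorithms),
            "hallmark_path": self.hallmark_path,
            "extraction_params": dict(self.extraction_params),
            "analyses": list(self.analyses),
            "bland_altman_mode": self.bland_altman_mode,
            "rf_top_k": self.rf_top_k,
            "rf_ntree": self.rf_ntree,
            "max_k": self.max_k,
            "write_models": self.write_models,
            "seed": self.seed,
        }

    @classmethod
    def from_json(cls, path: str | Path) -> "BenchmarkConfig":
        payload = json.loads(Path(path).read_text())
        payload["datasets"] = tuple(DatasetSpec(**d) for d in payload["datasets"])
        return cls(**payload)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_json_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class HeterogeneityReport:
    """Collected outputs of one benchmark run."""

    config_hash: str
    scores: pd.DataFrame
    jaccard: pd.DataFrame
    bland_altman: pd.DataFrame
    disagreement: pd.DataFrame
    clusters: dict
    importances: dict
    barcode: pd.Series | None
    failures: list[dict]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _load_profiles(spec: DatasetSpec):
    raw = read_expression_tsv(spec.expression_path)
    meta = read_metadata_tsv(spec.metadata_path)
    replicate_groups = dict(zip(meta["column"], meta["sample"]))
    platforms = dict(zip(meta["sample"], meta["platform"]))
    groups = dict(zip(meta["sample"], meta["group"]))
    return preprocess(raw, replicate_groups, platforms, groups)


def run_benchmark(cfg: BenchmarkConfig) -> HeterogeneityReport:
    """Run the dataset x algorithm benchmark described by ``cfg``.

    Stage order: load -> FASTCC -> per-sample mapping -> extraction -> FBA ->
    scores -> pairwise metrics -> PCA/RF (skipped, with a log entry, for cells
    that do not separate into two or more clusters).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(cfg.to_json_dict(), indent=1, sort_keys=True) + "\n"
    )
    config_hash = cfg.config_hash()

    raw_model = load_model(cfg.model_path)
    consistency = fastcc(raw_model)
    model = raw_model.submodel(
        consistency.consistent_reactions, model_id=raw_model.model_id
    )
    model.objective_reaction = (
        raw_model.objective_reaction
        if raw_model.objective_reaction in consistency.consistent_reactions
        else None
    )
    logger.info(
        "model %s: %d/%d reactions flux-consistent",
        model.model_id, len(model.reactions), len(raw_model.reactions),
    )

    if cfg.hallmark_path:
        hallmark = read_gene_list(cfg.hallmark_path)
    else:
        hallmark = hallmark_gene_list(model)

    aliases = DEFAULT_ALIASES
    protected = protect_reactions(
        model, aliases.protected_set() & set(model.reaction_ids)
    )

    score_rows: list[dict] = []
    jaccard_rows: list[dict] = []
    ba_rows: list[dict] = []
    disagreement_rows: list[dict] = []
    failures: list[dict] = []
    clusters: dict[str, dict] = {}
    importances: dict[str, object] = {}
    importance_rows: list[dict] = []

    for spec in cfg.datasets:
        profiles = _load_profiles(spec)
        for algorithm in cfg.algorithms:
            cell = f"{spec.name}_{algorithm}"
            cell_dir = out / "cells" / cell
            ext_cfg = ExtractionConfig(
                algorithm=algorithm, protected=protected, **cfg.extraction_params
            )
            results, states = [], []
            for profile in profiles:
                try:
                    activity = map_expression(model, profile)
                    result = extract(model, activity, ext_cfg)
                    state = fba(result.context_model)
                except Exception as exc:  # per-sample robustness
                    logger.warning("%s/%s failed: %s", cell, profile.sample_id, exc)
                    failures.append(
                        {
                            "cell": cell,
                            "sample": profile.sample_id,
                            "error": f"{type(exc).__name__}: {exc}",
                        }
                    )
                    continue
                results.append(result)
                states.append(state)
                report = score_cgem(result, state, hallmark, aliases)
                score_rows.append(
                    {
                        "dataset": spec.name,
                        "algorithm": algorithm,
                        "sample": profile.sample_id,
                        "group": profile.group_label or "",
                        "n_reactions": len(result.kept_reactions),
                        "objective": state.objective_value,
                        "afr": report.afr,
                        "eor": report.eor,
                        "hallmark_percent": report.hallmark_percent,
                        "flags": ";".join(report.flags),
                        "solver_status": state.status,
                        "config_hash": config_hash,
                    }
                )
                logger.info(
                    "cgem cell=%s sample=%s status=%s seed=%d hash=%s",
                    cell, profile.sample_id, state.status, cfg.seed, config_hash,
                )
            if cfg.write_models and results:
                models_dir = cell_dir / "models"
                models_dir.mkdir(parents=True, exist_ok=True)
                for result in results:
                    save_model(
                        result.context_model,
                        models_dir / f"{result.sample_id}.json",
                    )
            if not results:
                continue

            if "jaccard" in cfg.analyses:
                for i in range(len(results)):
                    for j in range(i + 1, len(results)):
                        rep = jaccard_subsystem(results[i], results[j], model)
                        jaccard_rows.append(
                            {
                                "dataset": spec.name,
                                "algorithm": algorithm,
                                "sample_a": rep.pair[0],
                                "sample_b": rep.pair[1],
                                "mean_index": rep.mean_index,
                            }
                        )
            if "bland_altman" in cfg.analyses and len(states) >= 2:
                named = [
                    _rename_state(s, r.sample_id) for s, r in zip(states, results)
                ]
                pct, table = disagreement_matrix(
                    named, alpha=0.05, mode=cfg.bland_altman_mode
                )
                disagreement_rows.append(
                    {
                        "dataset": spec.name,
                        "algorithm": algorithm,
                        "percent_significant": pct,
                        "n_pairs": len(table),
                    }
                )
                for rec in table.to_dict("records"):
                    rec.update({"dataset": spec.name, "algorithm": algorithm})
                    ba_rows.append(rec)

            if "pca_rf" in cfg.analyses and len(states) >= 3:
                sample_ids = [r.sample_id for r in results]
                fm = build_flux_matrix(
                    states, model.reaction_ids, sample_ids=sample_ids
                )
                cluster_report = pca_cluster(
                    fm, max_k=cfg.max_k, random_state=cfg.seed
                )
                clusters[cell] = {
                    "n_clusters": cluster_report.n_clusters,
                    "silhouette": cluster_report.silhouette,
                    "labels": cluster_report.labels,
                    "explained_variance_first2": (
                        sum(cluster_report.explained_variance[:2])
                        if cluster_report.explained_variance
                        else None
                    ),
                }
                if cluster_report.n_clusters >= 2:
                    imp = rf_importance(
                        fm,
                        cluster_report.labels,
                        model=model,
                        ntree=cfg.rf_ntree,
                        k=cfg.rf_top_k,
                        random_state=cfg.seed,
                    )
                    importances[cell] = imp
                    for rank, rid in enumerate(imp.top_k, start=1):
                        importance_rows.append(
                            {
                                "dataset": spec.name,
                                "algorithm": algorithm,
                                "rank": rank,
                                "reaction": rid,
                                "importance": float(imp.importances[rid]),
                                "subsystem": model.reaction(rid).subsystem,
                            }
                        )
                else:
                    logger.info("cell %s: <2 clusters, RF skipped", cell)

    scores = pd.DataFrame(score_rows)
    jaccard = pd.DataFrame(jaccard_rows)
    ba = pd.DataFrame(ba_rows)
    disagreement = pd.DataFrame(disagreement_rows)
    barcode = (
        subsystem_barcode(list(importances.values()), model)
        if importances
        else None
    )

    _write_tsv(scores, out / "scores.tsv")
    _write_tsv(jaccard, out / "jaccard.tsv")
    _write_tsv(ba, out / "bland_altman.tsv")
    _write_tsv(disagreement, out / "disagreement.tsv")
    _write_tsv(pd.DataFrame(importance_rows), out / "importance.tsv")
    if barcode is not None:
        _write_tsv(
            barcode.rename("count").rename_axis("subsystem").reset_index(),
            out / "barcode.tsv",
        )
    summary = {
        "config_hash": config_hash,
        "seed": cfg.seed,
        "n_cgems": len(score_rows),
        "n_failures": len(failures),
        "failures": failures,
        "clusters": clusters,
        "barcode": barcode.to_dict() if barcode is not None else {},
        "model": {
            "model_id": model.model_id,
            "n_reactions": len(model.reactions),
            "n_removed_inconsistent": len(consistency.removed_reactions),
        },
    }
    (out / "report.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=_json_default) + "\n"
    )
    return HeterogeneityReport(
        config_hash=config_hash,
        scores=scores,
        jaccard=jaccard,
        bland_altman=ba,
        disagreement=disagreement,
        clusters=clusters,
        importances=importances,
        barcode=barcode,
        failures=failures,
    )


def _rename_state(state, name: str):
    from dataclasses import replace

    return replace(state, model_id=name)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
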