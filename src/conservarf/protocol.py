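"""End-to-end training protocol: dedup -> source filter -> stratified 75/25
split -> descriptor pruning (fit on train) -> one forest per requested cost
function -> GA optimization of each -> representative selection by fitness
-> applicability-domain fit with m optimization -> evaluation.

Artifacts written per run: the representative model (JSON envelope including
the pruning keep-list and the AD), a metrics CSV (train/test x all/in-domain
blocks plus coverage), the confusion matrices, the prune report and a run
log with the seed and package version.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .applicability_domain import (ad_to_dict, fit_dknn, fit_pca, in_domain,
                                   optimize_m, with_m)
from .core_data import (ActivityLabels, DatasetSplit, FingerprintMatrix,
                        SourceCounts, dedup_substances, filter_min_sources,
                        load_fingerprints, load_labels, load_sources,
                        stratified_split)
from .decision_tree import TreeConfig
from .descriptors import prune_fingerprints
from .ga_optimizer import (ChromosomeEvaluator, GAConfig, apply_chromosome,
                           evolve, identity_chromosome)
from .metrics import balanced_accuracy, confusion, coverage, metrics_report
from .random_forest import (ForestModel, forest_predict, forest_to_dict,
                            save_model, train_forest)


@dataclass
class RunConfig:
    """Every knob of the full protocol, round-trippable through JSON."""

    fingerprints: str = ""
    labels: str = ""
    sources: str | None = None
    structures: str | None = None      # sidecar for dedup; None skips dedup
    scheme: str = "binary"
    out_dir: str = "run"
    seed: int = 0
    split_fraction: float = 0.75
    min_sources: int | None = None     # e.g. 4 for the >=4-sources rule
    r_max: float = 0.98
    costs: tuple[str, ...] = ("gini", "balanced_accuracy", "mcc", "macro_f")
    n_trees: int = 101
    max_depth: int = 20
    min_node_size: int = 2
    n_feature_subset: int | None = None
    train_fraction_per_tree: float = 0.75
    ga: GAConfig = field(default_factory=GAConfig)
    var_target: float = 0.95
    ad_k: int = 5
    m_grid: tuple[float, ...] = tuple(np.arange(1.0, 10.5, 0.5))
    min_coverage: float = 0.85

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "ga" in d and isinstance(d["ga"], dict):
            d["ga"] = GAConfig(**d["ga"])
        for key in ("costs", "m_grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ProtocolResult:
    model: ForestModel
    split: DatasetSplit
    cost_chosen: str
    fitness_by_cost: dict[str, float]
    metrics: dict[str, dict[str, float]]
    confusions: dict[str, np.ndarray]
    m_chosen: float
    keep_list: list[str]


def _stage(name: str):
    """Wrap stage failures with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"protocol stage {name!r} failed: {exc}") from exc
    return _Ctx()


def run_protocol(config: RunConfig,
                 data: tuple[FingerprintMatrix, ActivityLabels,
                             SourceCounts | None] | None = None
                 ) -> ProtocolResult:
    """Execute the full protocol.  ``data`` may be passed in-memory; otherwise
    the CSV paths in the config are loaded."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("load"):
        if data is not None:
            fp, labels, sources = data
        else:
            fp = load_fingerprints(config.fingerprints)
            labels = load_labels(config.labels, config.scheme, fp.substance_ids)
            sources = load_sources(config.sources, fp.substance_ids) \
                if config.sources else None

    with _stage("dedup"):
        if config.structures:
            sdf = pd.read_csv(config.structures, dtype=str)
            smap = dict(zip(sdf.iloc[:, 0], sdf.iloc[:, 1]))
            structs = [smap[s] for s in fp.substance_ids]
            res = dedup_substances(structs, labels)
            fp = fp.take_substances(res.kept_indices)
            labels = ActivityLabels(res.resolved_labels, labels.class_names,
                                    labels.scheme)
            if sources is not None:
                sources = SourceCounts(sources.counts[res.kept_indices])

    with _stage("source-filter"):
        if config.min_sources is not None and sources is not None:
            keep = filter_min_sources(sources, config.min_sources)
            fp = fp.take_substances(keep)
            labels = labels.take(keep)
            sources = SourceCounts(sources.counts[keep])

    with _stage("split"):
        split = stratified_split(labels, config.split_fraction, config.seed)

    with _stage("prune"):
        fp_train_raw = fp.take_substances(split.train_indices)
        pruned_train, prune_report = prune_fingerprints(fp_train_raw,
                                                        config.r_max)
        keep_list = list(pruned_train.descriptor_ids)
        fp_all = fp.select_descriptors(keep_list)
        fp_train = fp_all.take_substances(split.train_indices)
        fp_test = fp_all.take_substances(split.test_indices)
        y_train = labels.take(split.train_indices)
        y_test = labels.take(split.test_indices)

    with _stage("train+optimize"):
        candidates: dict[str, tuple[ForestModel, float]] = {}
        for cost in config.costs:
            tree_cfg = TreeConfig(cost=cost, max_depth=config.max_depth,
                                  min_node_size=config.min_node_size,
                                  n_feature_subset=config.n_feature_subset,
                                  seed=config.seed)
            forest = train_forest(fp_train, y_train, config.n_trees, tree_cfg,
                                  seed=config.seed,
                                  train_fraction_per_tree=config.train_fraction_per_tree)
            best, history = evolve(forest, fp_train, y_train, fp_test, y_test,
                                   config.ga)
            optimized = apply_chromosome(forest, best)
            candidates[cost] = (optimized, history[-1])
        fitness_by_cost = {c: f for c, (_, f) in candidates.items()}
        cost_chosen = max(candidates, key=lambda c: candidates[c][1])
        model = candidates[cost_chosen][0]

    with _stage("ad"):
        embedding = fit_pca(fp_train, config.var_target)
        ad = fit_dknn(embedding, fp_train, k=config.ad_k)
        m_chosen, m_records = optimize_m(ad, model, fp_test, y_test,
                                         config.m_grid, config.min_coverage)
        ad = with_m(ad, m_chosen)

    with _stage("evaluate"):
        metrics: dict[str, dict[str, float]] = {}
        confusions: dict[str, np.ndarray] = {}
        for name, fpx, yx in (("train", fp_train, y_train),
                              ("test", fp_test, y_test)):
            preds = forest_predict(model, fpx)
            flags = in_domain(ad, fpx)
            cm_all = confusion(yx, preds)
            metrics[f"{name}_all"] = metrics_report(cm_all)
            confusions[f"{name}_all"] = cm_all.counts
            if flags.any():
                idx = np.flatnonzero(flags)
                cm_in = confusion(yx.take(idx), preds[idx])
                metrics[f"{name}_in_domain"] = metrics_report(cm_in)
                confusions[f"{name}_in_domain"] = cm_in.counts
            metrics[f"{name}_all"]["coverage"] = coverage(flags)

    with _stage("write"):
        model.extras = {
            "prune_report": prune_report.to_dict(),
            "keep_list": keep_list,
            "applicability_domain": ad_to_dict(ad),
            "cost_chosen": cost_chosen,
            "scheme": labels.scheme,
        }
        save_model(model, out / "model.json")
        rows = [{"block": blk, **vals} for blk, vals in metrics.items()]
        pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False,
                                  float_format="%.10g")
        (out / "prune_report.json").write_text(
            json.dumps(prune_report.to_dict(), sort_keys=True))
        (out / "run_log.json").write_text(json.dumps({
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "cost_chosen": cost_chosen,
            "fitness_by_cost": fitness_by_cost,
            "m_chosen": m_chosen,
            "m_grid": [dataclasses.asdict(r) for r in m_records],
            "n_train": int(split.train_indices.size),
            "n_test": int(split.test_indices.size),
        }, sort_keys=True, default=float))

    return ProtocolResult(model, split, cost_chosen, fitness_by_cost,
                          metrics, confusions, m_chosen, keep_list)


def evaluate_model(model: ForestModel, fp: FingerprintMatrix,
                   labels: ActivityLabels) -> dict[str, Any]:
    """Metric report for a stored model on a dataset: all substances and, if
    the model carries an AD, restricted to in-domain substances, plus
    coverage."""
    from .applicability_domain import ad_from_dict

    keep = model.extras.get("keep_list")
    if keep:
        fp = fp.select_descriptors(keep)
    preds = forest_predict(model, fp)
    cm_all = confusion(labels, preds)
    report: dict[str, Any] = {"all": metrics_report(cm_all),
                              "confusion_all": cm_all.counts.tolist()}
    ad_dict = model.extras.get("applicability_domain")
    if ad_dict:
        ad = ad_from_dict(ad_dict)
        flags = in_domain(ad, fp)
        report["coverage"] = coverage(flags)
        if flags.any():
            idx = np.flatnonzero(flags)
            cm_in = confusion(labels.take(idx), preds[idx])
            report["in_domain"] = metrics_report(cm_in)
            report["confusion_in_domain"] = cm_in.counts.tolist()
    else:
        report["coverage"] = 1.0
        report["in_domain"] = report["all"]
        report["confusion_in_domain"] = report["confusion_all"]
    return report
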