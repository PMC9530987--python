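"""Conservative random forest: an ordered ensemble of bespoke decision trees
with a per-tree enabled flag and depth cap (the genetic-algorithm chromosome
acts on exactly those two fields) and conservative majority voting — vote
ties resolve toward the stronger activity class, so an Inactive/Active tie
predicts Active.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from .core_data import ActivityLabels, FingerprintMatrix
from .decision_tree import (TreeConfig, TreeNode, grow_tree,
                            predict_tree_batch, tree_from_dict, tree_to_dict)

DEFAULT_N_TREES = 101


@dataclass
class ForestModel:
    trees: list[TreeNode]
    enabled: np.ndarray            # per-tree bool
    depth_cap: list[int | None]    # per-tree cap; None = uncapped
    class_names: tuple[str, ...]
    descriptor_ids: list[str]
    config: TreeConfig
    train_fraction_per_tree: float
    seed: int
    extras: dict[str, Any] = field(default_factory=dict)  # prune report, AD, ...

    def __post_init__(self) -> None:
        self.enabled = np.asarray(self.enabled, dtype=bool)
        if not (len(self.trees) == self.enabled.size == len(self.depth_cap)):
            raise ValueError("trees / enabled / depth_cap lengths differ")
        if len(self.trees) and not self.enabled.any():
            raise ValueError("a forest needs at least one enabled tree")

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


def train_forest(fp: FingerprintMatrix, labels: ActivityLabels,
                 n_trees: int = DEFAULT_N_TREES,
                 config: TreeConfig | None = None, seed: int = 0,
                 train_fraction_per_tree: float = 0.75) -> ForestModel:
    """Train ``n_trees`` trees, each on an independently drawn random subset
    (without replacement) of the training substances.

    Each tree's RNG stream is derived from ``(seed, tree_index)``, so training
    is reproducible and trees are independent of training order.  A subset
    that misses a class is redrawn up to 10 times before proceeding with a
    warning.
    """
    if fp.n_substances == 0:
        raise ValueError("empty training data")
    y = labels.labels
    k = labels.n_classes
    present = set(np.unique(y).tolist())
    if len(present) < k:
        missing = [labels.class_names[c] for c in range(k) if c not in present]
        raise ValueError(f"training data is missing classes {missing}")
    if config is None:
        config = TreeConfig()
    n = fp.n_substances
    n_sub = max(2, int(np.floor(train_fraction_per_tree * n)))
    trees: list[TreeNode] = []
    for i in range(n_trees):
        rng = np.random.default_rng([seed, i])
        subset = rng.choice(n, size=n_sub, replace=False)
        for _ in range(10):
            if len(np.unique(y[subset])) == k:
                break
            subset = rng.choice(n, size=n_sub, replace=False)
        else:
            warnings.warn(f"tree {i}: subset missing a class after 10 redraws",
                          stacklevel=2)
        trees.append(grow_tree(subset, fp, y, config, k, rng))
    return ForestModel(
        trees=trees,
        enabled=np.ones(n_trees, dtype=bool),
        depth_cap=[None] * n_trees,
        class_names=labels.class_names,
        descriptor_ids=list(fp.descriptor_ids),
        config=config,
        train_fraction_per_tree=train_fraction_per_tree,
        seed=seed,
    )


def conservative_vote(tally: Sequence[int]) -> int:
    """Class with the maximum vote count; among tied maxima the strongest
    (highest-index) class wins."""
    t = np.asarray(tally)
    if t.sum() <= 0:
        raise ValueError("empty vote tally")
    return int(len(t) - 1 - np.argmax(t[::-1]))


def _check_descriptors(model: ForestModel, fp: FingerprintMatrix) -> None:
    if list(fp.descriptor_ids) != model.descriptor_ids:
        missing = sorted(set(model.descriptor_ids) - set(fp.descriptor_ids))
        if missing:
            raise ValueError(f"query data is missing descriptors {missing[:10]}"
                             + ("..." if len(missing) > 10 else ""))
        raise ValueError("descriptor order differs from training; reorder "
                         "columns to match the model's descriptor_ids")


def forest_predict(model: ForestModel, fp: FingerprintMatrix) -> np.ndarray:
    """Conservative-majority-vote predictions for every substance."""
    _check_descriptors(model, fp)
    return _predict_matrix(model, fp.values)


def _predict_matrix(model: ForestModel, X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    k = model.n_classes
    tallies = np.zeros((n, k), dtype=int)
    for tree, on, cap in zip(model.trees, model.enabled, model.depth_cap):
        if not on:
            continue
        preds = predict_tree_batch(tree, X, cap)
        tallies[np.arange(n), preds] += 1
    assert (tallies.sum(axis=1) == int(model.enabled.sum())).all()
    # highest-index maximum = conservative vote, vectorized
    return (k - 1 - np.argmax(tallies[:, ::-1], axis=1)).astype(int)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

FORMAT_VERSION = 1


def forest_to_dict(model: ForestModel) -> dict[str, Any]:
    return {
        "format_version": FORMAT_VERSION,
        "class_names": list(model.class_names),
        "descriptor_ids": list(model.descriptor_ids),
        "config": asdict(model.config),
        "train_fraction_per_tree": model.train_fraction_per_tree,
        "seed": model.seed,
        "enabled": [bool(e) for e in model.enabled],
        "depth_cap": [None if c is None else int(c) for c in model.depth_cap],
        "trees": [tree_to_dict(t) for t in model.trees],
        "extras": model.extras,
    }


def forest_from_dict(d: dict[str, Any]) -> ForestModel:
    return ForestModel(
        trees=[tree_from_dict(t) for t in d["trees"]],
        enabled=np.asarray(d["enabled"], dtype=bool),
        depth_cap=[None if c is None else int(c) for c in d["depth_cap"]],
        class_names=tuple(d["class_names"]),
        descriptor_ids=list(d["descriptor_ids"]),
        config=TreeConfig(**d["config"]),
        train_fraction_per_tree=float(d["train_fraction_per_tree"]),
        seed=int(d["seed"]),
        extras=d.get("extras", {}),
    )


def save_model(model: ForestModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(forest_to_dict(model), sort_keys=True))


def load_model(path: str | Path) -> ForestModel:
    return forest_from_dict(json.loads(Path(path).read_text()))
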