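"""Bespoke decision-tree learner for conservative activity screening.

Differences from a textbook CART tree, all deliberate:

* Continuous descriptors are binned once per tree into 20 equal-width bins
  over the tree's own training sample; only the internal bin boundaries are
  candidate thresholds (a molar-mass range of 50-250 yields candidates at
  60, 70, ..., 240).  Binary bits are tested at their single 0/1 split.
* The split score is pluggable: classical Gini impurity, or a classification
  metric (balanced accuracy, Matthews correlation, macro F) evaluated on the
  two-child conservative-majority labeling of the node's samples — the
  metric costs are what make the trees imbalance-aware.
* Every node (not just leaves) stores its class-count vector, so a tree can
  be depth-capped *after* training: prediction stops at the cap and returns
  the node's conservative majority.  Ties in a majority always resolve to
  the stronger activity class (higher class index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .core_data import BINARY, FingerprintMatrix

COST_FUNCTIONS = ("gini", "balanced_accuracy", "mcc", "macro_f")

# strict-improvement guard for split acceptance
_EPS = 1e-12


@dataclass
class TreeConfig:
    cost: str = "gini"
    max_depth: int = 20
    n_feature_subset: int | None = None  # None -> ceil(sqrt(n_descriptors))
    min_node_size: int = 2
    n_bins: int = 20
    f_beta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cost not in COST_FUNCTIONS:
            raise ValueError(f"unknown cost {self.cost!r}; pick from {COST_FUNCTIONS}")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.n_feature_subset is not None and self.n_feature_subset < 1:
            raise ValueError("n_feature_subset must be >= 1")

    def resolve_subset_size(self, n_descriptors: int) -> int:
        if self.n_feature_subset is not None:
            return min(self.n_feature_subset, n_descriptors)
        return min(int(np.ceil(np.sqrt(n_descriptors))), n_descriptors)


@dataclass
class TreeNode:
    """Internal node (descriptor test, two children) or leaf.

    ``class_counts`` is stored at every node so depth-capped prediction can
    stop anywhere and still return a conservative majority.
    """

    class_counts: np.ndarray
    feature: int | None = None
    descriptor_id: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None   # values <= threshold
    right: "TreeNode | None" = None  # values > threshold

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())


def conservative_majority(counts: np.ndarray) -> int:
    """Index of the largest count; ties resolve to the *highest* index,
    i.e. the stronger activity class."""
    counts = np.asarray(counts)
    return int(len(counts) - 1 - np.argmax(counts[::-1]))


def compute_bins(values: Sequence[float], n_bins: int = 20) -> np.ndarray:
    """Internal boundaries of ``n_bins`` equal-width bins over the sample
    range.  Returns an empty array when the sample is constant (the
    descriptor is unusable for splitting in this tree)."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    vmin, vmax = float(v.min()), float(v.max())
    if vmin == vmax:
        return np.array([], dtype=float)
    return vmin + (vmax - vmin) * np.arange(1, n_bins) / n_bins


class BinningScheme:
    """Per-tree candidate thresholds: equal-width bin boundaries for
    continuous descriptors, the single 0/1 midpoint for binary bits."""

    def __init__(self, fp: FingerprintMatrix, sample: np.ndarray,
                 n_bins: int = 20):
        self.boundaries: list[np.ndarray] = []
        sub = fp.values[sample]
        for j, kind in enumerate(fp.descriptor_kind):
            if kind == BINARY:
                self.boundaries.append(np.array([0.5]))
            else:
                self.boundaries.append(compute_bins(sub[:, j], n_bins))


# ---------------------------------------------------------------------------
# split scoring
# ---------------------------------------------------------------------------

def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p * p).sum())


def _induced_confusion(group_counts: list[np.ndarray]) -> np.ndarray:
    """Confusion matrix when each group's samples are all assigned the
    group's conservative-majority class."""
    k = len(group_counts[0])
    cm = np.zeros((k, k), dtype=float)
    for counts in group_counts:
        if counts.sum() == 0:
            continue
        cm[:, conservative_majority(counts)] += counts
    return cm

def _metric_of_confusion(cost: str, cm: np.ndarray, f_beta: float) -> float:
    present = cm.sum(axis=1) > 0
    if cost == "balanced_accuracy":
        rec = np.diag(cm)[present] / cm.sum(axis=1)[present]
        return float(rec.mean())
    if cost == "mcc":
        t = cm.sum(axis=1)
        p = cm.sum(axis=0)
        s = cm.sum()
        num = np.trace(cm) * s - float(t @ p)
        den = np.sqrt(s * s - float(p @ p)) * np.sqrt(s * s - float(t @ t))
        return float(num / den) if den > 0 else 0.0
    if cost == "macro_f":
        # averaged over classes present at the node
        tp = np.diag(cm)
        fp_ = cm.sum(axis=0) - tp
        fn_ = cm.sum(axis=1) - tp
        b2 = f_beta * f_beta
        denom = (1 + b2) * tp + b2 * fn_ + fp_
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(denom > 0, (1 + b2) * tp / denom, 0.0)
        return float(f[present].mean())
    raise ValueError(f"unknown metric cost {cost!r}")


def _score_groups(cost: str, group_counts: list[np.ndarray],
                  f_beta: float = 1.0) -> float:
    """Oriented (higher is better) score of a partition given per-group
    class-count vectors."""
    if cost == "gini":
        n = sum(int(c.sum()) for c in group_counts)
        w = sum(c.sum() * _gini(c) for c in group_counts) / n
        return -float(w)
    cm = _induced_confusion(group_counts)
    return _metric_of_confusion(cost, cm, f_beta)


def split_cost(cost: str, observed: Sequence[int], groups: Sequence[int],
               n_classes: int, *, oriented: bool = False,
               f_beta: float = 1.0) -> float:
    """Score a candidate partition of a node's samples.

    ``groups`` assigns each sample to a child (any group ids); each child's
    samples are labeled with that child's conservative-majority class.  For
    ``gini`` the raw value is the weighted mean of child impurities (lower is
    better); the metric costs return the metric of the induced labeling
    (higher is better).  ``oriented=True`` normalizes everything to
    higher-is-better by negating Gini.
    """
    y = np.asarray(observed, dtype=int)
    g = np.asarray(groups, dtype=int)
    if y.shape != g.shape:
        raise ValueError("observed and groups lengths differ")
    group_counts = [np.bincount(y[g == gid], minlength=n_classes)
                    for gid in np.unique(g)]
    score = _score_groups(cost, group_counts, f_beta)
    if cost == "gini" and not oriented:
        return -score
    return score


# ---------------------------------------------------------------------------
# split search
# ---------------------------------------------------------------------------

def _class_bin_counts(v: np.ndarray, y: np.ndarray, boundaries: np.ndarray,
                      k: int) -> np.ndarray:
    """counts[c, b]: class-c samples whose value falls in bin b, where bin b
    collects values <= boundaries[b] (and the last bin the remainder)."""
    # side='left': a value equal to boundary b lands in bin b, so the
    # cumulative count through bin b includes it — matching v <= b going left
    bin_idx = np.searchsorted(boundaries, v, side="left")
    counts = np.zeros((k, len(boundaries) + 1), dtype=np.int64)
    np.add.at(counts, (y, bin_idx), 1)
    return counts


def best_split(samples: np.ndarray, fp: FingerprintMatrix, y_all: np.ndarray,
               bins: BinningScheme, config: TreeConfig, rng: np.random.Generator,
               n_classes: int) -> tuple[int, float] | None:
    """Best (feature, threshold) over a fresh random descriptor subset, or
    None when no candidate strictly improves on the unsplit node.

    Ties between candidates resolve to the lowest descriptor index, then the
    lowest threshold (the subset is scanned in sorted order).
    """
    y = y_all[samples]
    n = y.size
    node_counts = np.bincount(y, minlength=n_classes)
    d = fp.n_descriptors
    subset = np.sort(rng.choice(d, size=config.resolve_subset_size(d),
                                replace=False))
    unsplit = _score_groups(config.cost, [node_counts], config.f_beta)
    best_score = unsplit + _EPS
    best: tuple[int, float] | None = None
    X = fp.values
    for j in subset:
        boundaries = bins.boundaries[j]
        if boundaries.size == 0:
            continue
        v = X[samples, j]
        counts = _class_bin_counts(v, y, boundaries, n_classes)
        left_cum = counts.cumsum(axis=1)
        for b, thr in enumerate(boundaries):
            left = left_cum[:, b]
            n_left = int(left.sum())
            if n_left == 0 or n_left == n:
                continue  # empty child: candidate rejected
            right = node_counts - left
            score = _score_groups(config.cost, [left, right], config.f_beta)
            if score > best_score:
                best_score = score
                best = (int(j), float(thr))
    return best


def grow_tree(samples: Sequence[int], fp: FingerprintMatrix,
              y_all: np.ndarray, config: TreeConfig, n_classes: int,
              rng: np.random.Generator | None = None) -> TreeNode:
    """Recursively grow a tree on ``samples``.

    Bins are computed once, from the tree's own sample, before any splitting;
    recursion stops at max_depth, node purity, min_node_size, or when no
    candidate split improves the cost.
    """
    samples = np.asarray(samples, dtype=int)
    if samples.size < 1:
        raise ValueError("cannot grow a tree on an empty sample")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    bins = BinningScheme(fp, samples, config.n_bins)

    def _grow(idx: np.ndarray, depth: int) -> TreeNode:
        counts = np.bincount(y_all[idx], minlength=n_classes)
        node = TreeNode(class_counts=counts)
        if (depth >= config.max_depth or idx.size < config.min_node_size
                or np.count_nonzero(counts) <= 1):
            return node
        found = best_split(idx, fp, y_all, bins, config, rng, n_classes)
        if found is None:
            return node
        j, thr = found
        mask = fp.values[idx, j] <= thr
        node.feature = j
        node.descriptor_id = fp.descriptor_ids[j]
        node.threshold = thr
        node.left = _grow(idx[mask], depth + 1)
        node.right = _grow(idx[~mask], depth + 1)
        return node

    return _grow(samples, 0)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_tree_batch(tree: TreeNode, X: np.ndarray,
                       depth_cap: int | None = None) -> np.ndarray:
    """Vectorized prediction: route all rows of ``X`` down the tree, stopping
    at ``depth_cap`` (0 = root), and return each stop node's conservative
    majority class."""
    n = X.shape[0]
    out = np.empty(n, dtype=int)

    def _route(node: TreeNode, idx: np.ndarray, depth: int) -> None:
        if node.is_leaf or (depth_cap is not None and depth >= depth_cap):
            out[idx] = conservative_majority(node.class_counts)
            return
        mask = X[idx, node.feature] <= node.threshold
        if mask.any():
            _route(node.left, idx[mask], depth + 1)
        if (~mask).any():
            _route(node.right, idx[~mask], depth + 1)

    _route(tree, np.arange(n), 0)
    return out


def predict_tree(tree: TreeNode, x: Sequence[float],
                 depth_cap: int | None = None) -> int:
    """Predict a single descriptor vector (see :func:`predict_tree_batch`)."""
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        raise ValueError("descriptor vector contains missing values")
    return int(predict_tree_batch(tree, x[None, :], depth_cap)[0])


# ---------------------------------------------------------------------------
# serialization (bit-exact JSON round-trip)
# ---------------------------------------------------------------------------

def tree_to_dict(node: TreeNode) -> dict[str, Any]:
    d: dict[str, Any] = {"class_counts": [int(c) for c in node.class_counts]}
    if not node.is_leaf:
        d.update(feature=int(node.feature),
                 descriptor_id=node.descriptor_id,
                 threshold=float(node.threshold),
                 left=tree_to_dict(node.left),
                 right=tree_to_dict(node.right))
    return d


def tree_from_dict(d: dict[str, Any]) -> TreeNode:
    node = TreeNode(class_counts=np.asarray(d["class_counts"], dtype=int))
    if "feature" in d:
        node.feature = int(d["feature"])
        node.descriptor_id = d["descriptor_id"]
        node.threshold = float(d["threshold"])
        node.left = tree_from_dict(d["left"])
        node.right = tree_from_dict(d["right"])
    return node
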