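"""Shared data model: fingerprint matrices, ordered activity labels,
dataset splitting, source-count filtering and structure deduplication.

The conventions used everywhere in the package:

* A fingerprint matrix is substances x descriptors, mostly binary
  substructure indicator bits plus a handful of continuous
  physical-chemical properties.
* Activity labels carry an explicit total order from weakest to strongest
  activity (``Inactive`` < ... < ``Strong``); the class *index* encodes the
  order, so "stronger" always means "higher index".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

BINARY_CLASSES = ("Inactive", "Active")
MULTICLASS5_CLASSES = ("Inactive", "Very Weak", "Weak", "Moderate", "Strong")

BINARY = "binary"
CONTINUOUS = "continuous"


def _check_unique(names: Sequence[str], what: str) -> None:
    if len(set(names)) != len(names):
        seen: set[str] = set()
        dup = next(n for n in names if n in seen or seen.add(n))
        raise ValueError(f"duplicate {what}: {dup!r}")


@dataclass
class FingerprintMatrix:
    """Substances x descriptors table with per-column kind flags.

    ``descriptor_kind[j]`` is ``"binary"`` (column restricted to {0, 1}) or
    ``"continuous"``.  Binary columns are validated on construction; missing
    values are never allowed.
    """

    substance_ids: list[str]
    values: np.ndarray
    descriptor_ids: list[str]
    descriptor_kind: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if n != len(self.substance_ids):
            raise ValueError("substance_ids length does not match values rows")
        if d != len(self.descriptor_ids) or d != len(self.descriptor_kind):
            raise ValueError("descriptor metadata length does not match values columns")
        _check_unique(self.substance_ids, "substance_id")
        _check_unique(self.descriptor_ids, "descriptor_id")
        bad_kind = set(self.descriptor_kind) - {BINARY, CONTINUOUS}
        if bad_kind:
            raise ValueError(f"unknown descriptor kind(s): {sorted(bad_kind)}")
        if np.isnan(self.values).any():
            raise ValueError("fingerprint matrix contains missing values")
        kinds = np.asarray(self.descriptor_kind)
        binary_cols = np.flatnonzero(kinds == BINARY)
        if binary_cols.size:
            sub = self.values[:, binary_cols]
            if not np.isin(sub, (0.0, 1.0)).all():
                j = binary_cols[np.flatnonzero(~np.isin(sub, (0.0, 1.0)).all(axis=0))[0]]
                raise ValueError(
                    f"binary descriptor {self.descriptor_ids[j]!r} has values outside {{0,1}}"
                )

    @property
    def n_substances(self) -> int:
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    def take_substances(self, indices: Sequence[int]) -> "FingerprintMatrix":
        idx = np.asarray(indices, dtype=int)
        return FingerprintMatrix(
            substance_ids=[self.substance_ids[i] for i in idx],
            values=self.values[idx],
            descriptor_ids=list(self.descriptor_ids),
            descriptor_kind=list(self.descriptor_kind),
        )

    def take_descriptors(self, indices: Sequence[int]) -> "FingerprintMatrix":
        idx = np.asarray(indices, dtype=int)
        return FingerprintMatrix(
            substance_ids=list(self.substance_ids),
            values=self.values[:, idx],
            descriptor_ids=[self.descriptor_ids[j] for j in idx],
            descriptor_kind=[self.descriptor_kind[j] for j in idx],
        )

    def select_descriptors(self, keep_ids: Sequence[str]) -> "FingerprintMatrix":
        """Project onto a learned keep-list (e.g. from pruning on train data)."""
        pos = {d: j for j, d in enumerate(self.descriptor_ids)}
        missing = [d for d in keep_ids if d not in pos]
        if missing:
            raise KeyError(f"descriptors not present: {missing[:5]}")
        return self.take_descriptors([pos[d] for d in keep_ids])


@dataclass
class ActivityLabels:
    """Per-substance class indices with an explicit weakest-to-strongest order."""

    labels: np.ndarray
    class_names: tuple[str, ...]
    scheme: str  # "binary" | "multiclass5"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.class_names = tuple(self.class_names)
        if self.scheme == "binary" and self.class_names != BINARY_CLASSES:
            raise ValueError("binary scheme requires classes (Inactive, Active)")
        if self.scheme == "multiclass5" and self.class_names != MULTICLASS5_CLASSES:
            raise ValueError(
                "multiclass5 scheme requires classes Inactive..Strong in order"
            )
        if self.scheme not in ("binary", "multiclass5"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= len(self.class_names)
        ):
            raise ValueError("class index out of range")

    @classmethod
    def binary(cls, labels: Sequence[int]) -> "ActivityLabels":
        return cls(np.asarray(labels), BINARY_CLASSES, "binary")

    @classmethod
    def multiclass5(cls, labels: Sequence[int]) -> "ActivityLabels":
        return cls(np.asarray(labels), MULTICLASS5_CLASSES, "multiclass5")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def take(self, indices: Sequence[int]) -> "ActivityLabels":
        return ActivityLabels(self.labels[np.asarray(indices, dtype=int)],
                              self.class_names, self.scheme)


@dataclass
class SourceCounts:
    """Per-substance number of independent data sources."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("source counts must be non-negative")


@dataclass
class DatasetSplit:
    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices, dtype=int)
        self.test_indices = np.asarray(self.test_indices, dtype=int)
        union = np.concatenate([self.train_indices, self.test_indices])
        if len(np.unique(union)) != union.size:
            raise ValueError("train and test indices overlap")


def stratified_split(labels: ActivityLabels, fraction: float = 0.75,
                     seed: int = 0) -> DatasetSplit:
    """Stratified train/test split: per class, floor(fraction * n_class)
    substances go to train (at least one, so every class is trainable).

    Deterministic for a fixed seed.  A class with a single member is placed
    entirely in train with a warning.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    y = labels.labels
    if y.size == 0:
        raise ValueError("empty label set")
    rng = np.random.default_rng(seed)
    train_parts: list[np.ndarray] = []
    test_parts: list[np.ndarray] = []
    for c in range(labels.n_classes):
        members = np.flatnonzero(y == c)
        if members.size == 0:
            continue
        if members.size == 1:
            warnings.warn(
                f"class {labels.class_names[c]!r} has a single member; "
                "placed in train", stacklevel=2)
        perm = rng.permutation(members)
        n_train = max(1, int(np.floor(fraction * members.size)))
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.concatenate(test_parts)) if any(
        p.size for p in test_parts) else np.array([], dtype=int)
    split = DatasetSplit(train, test, seed)
    assert np.array_equal(
        np.sort(np.concatenate([split.train_indices, split.test_indices])),
        np.arange(y.size))
    return split


def filter_min_sources(counts: SourceCounts, k: int) -> np.ndarray:
    """Indices of substances backed by at least ``k`` sources, order preserved."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return np.flatnonzero(counts.counts >= k)


@dataclass
class DedupResult:
    kept_indices: np.ndarray
    n_removed: int
    resolved_labels: np.ndarray | None = None


def dedup_substances(structures: Sequence[str],
                     labels: ActivityLabels | None = None) -> DedupResult:
    """Keep the first occurrence of each canonical structure string.

    When duplicates carry conflicting activity labels, the kept substance is
    assigned the strongest label observed among its duplicates (conservative
    conflict resolution).
    """
    first_pos: dict[str, int] = {}
    kept: list[int] = []
    for i, s in enumerate(structures):
        if s not in first_pos:
            first_pos[s] = i
            kept.append(i)
    kept_arr = np.asarray(kept, dtype=int)
    resolved = None
    if labels is not None:
        y = labels.labels
        strongest: dict[str, int] = {}
        for i, s in enumerate(structures):
            strongest[s] = max(strongest.get(s, -1), int(y[i]))
        resolved = np.asarray([strongest[structures[i]] for i in kept], dtype=int)
    return DedupResult(kept_arr, len(structures) - len(kept), resolved)


# ---------------------------------------------------------------------------
# CSV I/O (the package's on-disk dialect)
# ---------------------------------------------------------------------------

def infer_descriptor_kinds(values: np.ndarray) -> list[str]:
    """A column containing only {0, 1} is flagged binary, otherwise continuous."""
    kinds = []
    for j in range(values.shape[1]):
        col = values[:, j]
        finite = col[~np.isnan(col)]
        kinds.append(BINARY if np.isin(finite, (0.0, 1.0)).all() else CONTINUOUS)
    return kinds


def load_fingerprints(path: str | Path, *, on_missing: str = "error",
                      descriptor_kind: Sequence[str] | None = None) -> FingerprintMatrix:
    """Load the fingerprint CSV (first column substance_id, header row of
    descriptor ids).

    Missing values abort the load by default; ``on_missing="impute"`` fills
    continuous columns with their median and rejects missing binary bits.
    """
    df = pd.read_csv(path, dtype={0: str})
    ids = df.iloc[:, 0].tolist()
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    descriptor_ids = list(df.columns[1:])
    kinds = list(descriptor_kind) if descriptor_kind is not None \
        else infer_descriptor_kinds(values)
    if np.isnan(values).any():
        if on_missing == "impute":
            for j, kind in enumerate(kinds):
                col = values[:, j]
                if np.isnan(col).any():
                    if kind == BINARY:
                        raise ValueError(
                            f"binary descriptor {descriptor_ids[j]!r} has "
                            "missing values; imputation covers continuous only")
                    col[np.isnan(col)] = np.nanmedian(col)
        else:
            bad = [descriptor_ids[j] for j in
                   np.flatnonzero(np.isnan(values).any(axis=0))[:5]]
            raise ValueError(f"missing values in descriptors {bad}; "
                             "pass on_missing='impute' to fill continuous columns")
    return FingerprintMatrix(ids, values, descriptor_ids, kinds)


def save_fingerprints(fp: FingerprintMatrix, path: str | Path) -> None:
    df = pd.DataFrame(fp.values, columns=fp.descriptor_ids)
    df.insert(0, "substance_id", fp.substance_ids)
    df.to_csv(path, index=False)


def load_labels(path: str | Path, scheme: str,
                substance_ids: Sequence[str]) -> ActivityLabels:
    """Load the (substance_id, label) sidecar and align it to ``substance_ids``.

    Labels may be class names or integer indices.
    """
    class_names = BINARY_CLASSES if scheme == "binary" else MULTICLASS5_CLASSES
    df = pd.read_csv(path, dtype={0: str})
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    name_to_idx = {name: i for i, name in enumerate(class_names)}
    out = []
    for sid in substance_ids:
        if sid not in mapping:
            raise KeyError(f"no label for substance {sid!r}")
        raw = mapping[sid]
        out.append(name_to_idx[raw] if isinstance(raw, str) else int(raw))
    return ActivityLabels(np.asarray(out), class_names, scheme)


def save_labels(labels: ActivityLabels, substance_ids: Sequence[str],
                path: str | Path) -> None:
    pd.DataFrame({
        "substance_id": list(substance_ids),
        "label": [labels.class_names[c] for c in labels.labels],
    }).to_csv(path, index=False)


def load_sources(path: str | Path, substance_ids: Sequence[str]) -> SourceCounts:
    df = pd.read_csv(path, dtype={0: str})
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return SourceCounts(np.asarray([int(mapping[s]) for s in substance_ids]))


def save_sources(sources: SourceCounts, substance_ids: Sequence[str],
                 path: str | Path) -> None:
    pd.DataFrame({"substance_id": list(substance_ids),
                  "n_sources": sources.counts}).to_csv(path, index=False)
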