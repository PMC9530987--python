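"""Fingerprint assembly from descriptor-generator adapters and the two-step
descriptor pruning (zero variance, then Pearson collinearity).

The adapters are a contract, not an algorithm: anything mapping a SMILES
string to a fixed-width numeric vector with declared kinds qualifies — a
wrapper shelling out to an external fingerprint tool, or the bundled
:class:`RandomProjectionAdapter` which needs no external software and exists
so the assembly path is testable anywhere.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np

from .core_data import BINARY, CONTINUOUS, FingerprintMatrix

logger = logging.getLogger(__name__)


class DescriptorAdapter(Protocol):
    """Contract for one descriptor generator."""

    name: str
    width: int
    kinds: list[str]  # per-column, "binary" | "continuous"

    def compute(self, smiles: str) -> np.ndarray:
        """Fixed-width vector for one structure; raise on failure."""
        ...


@dataclass
class CallableAdapter:
    """Wrap any ``smiles -> vector`` callable as an adapter."""

    name: str
    width: int
    fn: Callable[[str], np.ndarray]
    kinds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.kinds:
            self.kinds = [BINARY] * self.width

    def compute(self, smiles: str) -> np.ndarray:
        v = np.asarray(self.fn(smiles), dtype=float)
        if v.shape != (self.width,):
            raise ValueError(f"adapter {self.name!r} returned width {v.shape}, "
                             f"declared {self.width}")
        return v


class RandomProjectionAdapter:
    """Hash-based pseudo-fingerprint: each bit is a deterministic hash of
    (structure string, bit index).  Chemically meaningless but structurally
    faithful (fixed width, binary, deterministic), so pipelines can be
    exercised without any external fingerprint tool."""

    def __init__(self, name: str = "randproj", width: int = 64):
        self.name = name
        self.width = width
        self.kinds = [BINARY] * width

    def compute(self, smiles: str) -> np.ndarray:
        digest = hashlib.sha256(smiles.encode()).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
        return (rng.random(self.width) < 0.5).astype(float)


def assemble_fingerprints(structures: Sequence[str],
                          generators: Sequence[DescriptorAdapter]
                          ) -> FingerprintMatrix:
    """Column-wise concatenation of every adapter's output, in declared
    adapter order, with descriptor ids prefixed by the generator name.

    A substance on which any adapter fails is dropped with a logged warning —
    never silently zero-filled.
    """
    descriptor_ids: list[str] = []
    kinds: list[str] = []
    for gen in generators:
        descriptor_ids += [f"{gen.name}:{j}" for j in range(gen.width)]
        kinds += list(gen.kinds)
    rows: list[np.ndarray] = []
    kept_ids: list[str] = []
    for i, smi in enumerate(structures):
        parts = []
        try:
            for gen in generators:
                parts.append(gen.compute(smi))
        except Exception as exc:  # noqa: BLE001 - adapter contract: any failure drops the row
            logger.warning("descriptor generation failed for %r: %s", smi, exc)
            continue
        rows.append(np.concatenate(parts) if parts else np.empty(0))
        kept_ids.append(f"s{i}")
    values = np.asarray(rows, dtype=float) if rows else \
        np.empty((0, len(descriptor_ids)))
    return FingerprintMatrix(kept_ids, values, descriptor_ids, kinds)


@dataclass
class PruneReport:
    removed_zero_variance: list[str]
    removed_correlated: list[tuple[str, str, float]]  # (kept, removed, r)
    n_before: int
    n_after: int

    def __post_init__(self) -> None:
        expected = self.n_before - len(self.removed_zero_variance) \
            - len(self.removed_correlated)
        if self.n_after != expected:
            raise ValueError("prune report counts are inconsistent")

    def to_dict(self) -> dict:
        return {
            "removed_zero_variance": self.removed_zero_variance,
            "removed_correlated": [
                {"kept": a, "removed": b, "r": r}
                for a, b, r in self.removed_correlated],
            "n_before": self.n_before,
            "n_after": self.n_after,
        }


def prune_zero_variance(fp: FingerprintMatrix
                        ) -> tuple[FingerprintMatrix, PruneReport]:
    """Drop descriptors constant across all substances."""
    if fp.n_substances < 1:
        raise ValueError("need at least one substance")
    varying = np.array([np.unique(fp.values[:, j]).size > 1
                        for j in range(fp.n_descriptors)])
    keep = np.flatnonzero(varying)
    removed = [fp.descriptor_ids[j] for j in np.flatnonzero(~varying)]
    report = PruneReport(removed, [], fp.n_descriptors, keep.size)
    return fp.take_descriptors(keep), report


def prune_correlated(fp: FingerprintMatrix, r_max: float = 0.98,
                     *, use_absolute: bool = True
                     ) -> tuple[FingerprintMatrix, PruneReport]:
    """Greedy left-to-right collinearity pruning: scanning columns in order,
    a column is dropped if it correlates with an already-kept column beyond
    ``r_max`` (|r| by default; ``use_absolute=False`` for signed r only).

    Requires zero-variance columns to be removed first (Pearson r is
    undefined for constant columns).
    """
    if not 0.0 < r_max <= 1.0:
        raise ValueError("r_max must be in (0, 1]")
    X = fp.values
    d = fp.n_descriptors
    stds = X.std(axis=0)
    if (stds == 0).any():
        j = int(np.flatnonzero(stds == 0)[0])
        raise ValueError(f"constant column {fp.descriptor_ids[j]!r}: run "
                         "prune_zero_variance first")
    Xc = (X - X.mean(axis=0)) / stds
    n = X.shape[0]
    kept: list[int] = []
    removed: list[tuple[str, str, float]] = []
    for j in range(d):
        culprit = None
        if kept:
            r = Xc[:, kept].T @ Xc[:, j] / n
            effective = np.abs(r) if use_absolute else r
            hits = np.flatnonzero(effective > r_max)
            if hits.size:
                culprit = (kept[int(hits[0])], float(r[int(hits[0])]))
        if culprit is None:
            kept.append(j)
        else:
            removed.append((fp.descriptor_ids[culprit[0]],
                            fp.descriptor_ids[j], culprit[1]))
    report = PruneReport([], removed, d, len(kept))
    return fp.take_descriptors(kept), report


def prune_fingerprints(fp: FingerprintMatrix, r_max: float = 0.98
                       ) -> tuple[FingerprintMatrix, PruneReport]:
    """Both pruning steps in order; the combined report keeps each step's
    removals.  Fit this on training data and apply the resulting keep-list
    (``pruned.descriptor_ids``) to test or new data."""
    fp1, rep1 = prune_zero_variance(fp)
    if fp1.n_descriptors == 0:
        warnings.warn("all descriptors were constant; empty matrix returned",
                      stacklevel=2)
        return fp1, rep1
    fp2, rep2 = prune_correlated(fp1, r_max)
    report = PruneReport(rep1.removed_zero_variance, rep2.removed_correlated,
                         fp.n_descriptors, fp2.n_descriptors)
    return fp2, report
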