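"""Density k-nearest-neighbor applicability domain (AD) on a PCA embedding.

The AD answers "is this query chemically similar enough to the training set
for the model's prediction to be trusted?".  Construction:

1. PCA on the pruned training fingerprints, keeping the smallest number of
   components whose cumulative explained variance reaches at least 95%.
2. For every embedded training point, the mean Euclidean distance to its k
   nearest training neighbors (excluding itself) — its raw admission radius.
   Dense regions get small radii, sparse regions large ones.
3. A global cap derived from the n^(1/m) rule, with n the number of training
   points and m a tunable looseness parameter: the cap is the
   ceil(n^(1/m))-th largest raw radius, and every per-point radius is clipped
   to it.  This trims the inflated radii of isolated training points; small m
   clips aggressively (tight domain), large m barely clips.
4. A query is in-domain iff it lies within the clipped radius of at least
   one training point.

``optimize_m`` scans a grid of m values and picks the one that maximizes
in-domain balanced accuracy subject to retaining at least a target fraction
(default 85%) of the evaluation substances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .core_data import ActivityLabels, FingerprintMatrix
from .metrics import balanced_accuracy, confusion, coverage
from .random_forest import ForestModel, forest_predict

DEFAULT_M_GRID = tuple(np.arange(1.0, 10.5, 0.5))


@dataclass
class PCAEmbedding:
    mean: np.ndarray
    components: np.ndarray  # (n_components, n_descriptors)
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.components.shape[1]:
            raise ValueError(
                f"query has {X.shape[1]} descriptors, embedding expects "
                f"{self.components.shape[1]}")
        return (X - self.mean) @ self.components.T


def fit_pca(fp: FingerprintMatrix | np.ndarray,
            var_target: float = 0.95) -> PCAEmbedding:
    """Smallest PCA basis whose cumulative explained-variance ratio reaches
    ``var_target``; component signs are fixed so the largest-magnitude
    loading of each component is positive (deterministic embedding)."""
    if not 0.0 < var_target <= 1.0:
        raise ValueError("var_target must be in (0, 1]")
    X = fp.values if isinstance(fp, FingerprintMatrix) else np.asarray(fp, float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two substances")
    pca = PCA(n_components=min(X.shape), svd_solver="full")
    pca.fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    r = int(np.searchsorted(cum, var_target - 1e-12) + 1)
    r = min(r, len(cum))
    components = pca.components_[:r].copy()
    for row in components:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PCAEmbedding(pca.mean_.copy(), components,
                        pca.explained_variance_ratio_[:r].copy())


def ad_threshold(n: int, m: float) -> float:
    """The n^(1/m) cut-off used to derive the global radius cap."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if m <= 0:
        raise ValueError("m must be > 0")
    return float(n ** (1.0 / m))


@dataclass
class ADModel:
    embedding: PCAEmbedding
    train_points: np.ndarray      # embedded training set
    k: int
    raw_radii: np.ndarray         # mean k-NN distance per training point
    m: float
    threshold: float              # n^(1/m)
    radii: np.ndarray             # raw radii clipped at the global cap

    @property
    def n_train(self) -> int:
        return self.train_points.shape[0]


def _mean_knn_radii(Z: np.ndarray, k: int) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Z)
    dist, _ = nn.kneighbors(Z)
    return dist[:, 1:].mean(axis=1)  # drop self-distance column


def _cap_radii(raw: np.ndarray, m: float) -> tuple[float, np.ndarray]:
    n = raw.size
    t = int(np.clip(math.ceil(ad_threshold(n, m)), 1, n))
    cap = float(np.sort(raw)[::-1][t - 1])  # t-th largest raw radius
    return cap, np.minimum(raw, cap)


def fit_dknn(embedding: PCAEmbedding, fp: FingerprintMatrix | np.ndarray,
             k: int = 5, m: float = 3.0) -> ADModel:
    """Fit the density-kNN domain on the training fingerprints."""
    X = fp.values if isinstance(fp, FingerprintMatrix) else np.asarray(fp, float)
    Z = embedding.transform(X)
    n = Z.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    raw = _mean_knn_radii(Z, k)
    _, radii = _cap_radii(raw, m)
    return ADModel(embedding, Z, k, raw, float(m), ad_threshold(n, m), radii)


def with_m(ad: ADModel, m: float) -> ADModel:
    """Re-derive the global cap for a different m without refitting
    neighbors (the raw radii depend only on k)."""
    _, radii = _cap_radii(ad.raw_radii, m)
    return ADModel(ad.embedding, ad.train_points, ad.k, ad.raw_radii,
                   float(m), ad_threshold(ad.n_train, m), radii)


def in_domain(ad: ADModel, queries: FingerprintMatrix | np.ndarray) -> np.ndarray:
    """True for each query within at least one training point's admission
    radius; queries are given in the original descriptor space."""
    X = queries.values if isinstance(queries, FingerprintMatrix) \
        else np.asarray(queries, float)
    Zq = ad.embedding.transform(X)
    r_max = float(ad.radii.max())
    nn = NearestNeighbors().fit(ad.train_points)
    dists, idxs = nn.radius_neighbors(Zq, radius=r_max)
    flags = np.zeros(Zq.shape[0], dtype=bool)
    for i, (d, j) in enumerate(zip(dists, idxs)):
        flags[i] = bool(d.size) and bool((d <= ad.radii[j]).any())
    return flags


@dataclass
class MGridRecord:
    m: float
    coverage: float
    ba_in_domain: float


def optimize_m(ad: ADModel, model: ForestModel, fp: FingerprintMatrix,
               labels: ActivityLabels,
               m_grid: Sequence[float] = DEFAULT_M_GRID,
               min_coverage: float = 0.85
               ) -> tuple[float, list[MGridRecord]]:
    """Choose m maximizing in-domain balanced accuracy subject to coverage
    >= ``min_coverage``.

    If no grid value meets the coverage constraint, the m with maximal
    coverage among the BA-improving values is returned (BA-improving
    relative to the no-domain baseline); ties always resolve to higher
    coverage.  Falls back to the maximal-coverage m if nothing improves BA.
    """
    m_grid = list(m_grid)
    if not m_grid:
        raise ValueError("m_grid must be non-empty")
    preds = forest_predict(model, fp)
    baseline = balanced_accuracy(confusion(labels, preds), ignore_empty=True)
    records: list[MGridRecord] = []
    for m in m_grid:
        flags = in_domain(with_m(ad, m), fp)
        cov = float(flags.mean())
        if flags.any():
            ba = balanced_accuracy(
                confusion(labels.take(np.flatnonzero(flags)),
                          preds[flags]), ignore_empty=True)
        else:
            ba = math.nan
        records.append(MGridRecord(float(m), cov, ba))
    feasible = [r for r in records if r.coverage >= min_coverage
                and not math.isnan(r.ba_in_domain)]
    if feasible:
        chosen = max(feasible, key=lambda r: (r.ba_in_domain, r.coverage))
        return chosen.m, records
    improving = [r for r in records if not math.isnan(r.ba_in_domain)
                 and r.ba_in_domain > baseline]
    pool = improving if improving else records
    chosen = max(pool, key=lambda r: (r.coverage,
                                      -math.inf if math.isnan(r.ba_in_domain)
                                      else r.ba_in_domain))
    return chosen.m, records


# ---------------------------------------------------------------------------
# serialization (stored inside the model JSON envelope)
# ---------------------------------------------------------------------------

def ad_to_dict(ad: ADModel) -> dict[str, Any]:
    return {
        "mean": ad.embedding.mean.tolist(),
        "components": ad.embedding.components.tolist(),
        "explained_variance_ratio": ad.embedding.explained_variance_ratio.tolist(),
        "train_points": ad.train_points.tolist(),
        "k": int(ad.k),
        "raw_radii": ad.raw_radii.tolist(),
        "m": float(ad.m),
        "threshold": float(ad.threshold),
        "radii": ad.radii.tolist(),
    }


def ad_from_dict(d: dict[str, Any]) -> ADModel:
    emb = PCAEmbedding(np.asarray(d["mean"], float),
                       np.asarray(d["components"], float),
                       np.asarray(d["explained_variance_ratio"], float))
    return ADModel(emb, np.asarray(d["train_points"], float), int(d["k"]),
                   np.asarray(d["raw_radii"], float), float(d["m"]),
                   float(d["threshold"]), np.asarray(d["radii"], float))
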