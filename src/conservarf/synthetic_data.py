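"""Synthetic fingerprint/label generator with the statistical structure the
screening method assumes: mostly-binary descriptors, a planted class signal
in a subset of bits, class-shifted continuous properties, severe class
imbalance, exact duplicate and constant columns (to exercise pruning), an
out-of-distribution contaminant block (to exercise the applicability
domain), and per-substance source counts.

Nothing here is chemically meaningful — the generator emulates the *shape*
of a curated receptor-activity dataset (a few thousand substances, ~95% of
them Inactive, a couple of thousand mostly-binary descriptors before
pruning), not real chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_data import (BINARY, BINARY_CLASSES, CONTINUOUS,
                        MULTICLASS5_CLASSES, ActivityLabels,
                        FingerprintMatrix, SourceCounts)

#: substance-id prefix marking out-of-distribution contaminants
OOD_PREFIX = "ood-"


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic dataset.

    ``bit_effect`` gives the per-class shift added to the 0.5 base success
    probability of every informative bit; ``continuous_effect`` is the
    per-class-step mean shift of the continuous descriptors (unit variance).
    """

    n_substances: int = 2000
    n_binary_descriptors: int = 185
    n_continuous_descriptors: int = 15
    class_priors: tuple[float, ...] = (0.9, 0.1)
    n_informative_bits: int | None = None  # None -> min(25, n_binary_descriptors)
    bit_effect: tuple[float, ...] | None = None  # None -> spread over (-0.25, +0.25)
    continuous_effect: float = 1.0
    n_duplicate_columns: int = 0
    n_constant_columns: int = 0
    contamination_fraction: float = 0.0
    source_count_distribution: tuple[str, float] = ("poisson", 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        priors = np.asarray(self.class_priors, dtype=float)
        if priors.size not in (2, 5) or (priors < 0).any():
            raise ValueError("class priors must be a 2-class or 5-class "
                             "non-negative vector")
        if abs(priors.sum() - 1.0) > 1e-9:
            raise ValueError("class priors must sum to 1")
        if self.n_informative_bits is None:
            self.n_informative_bits = min(25, self.n_binary_descriptors)
        if self.n_informative_bits > self.n_binary_descriptors:
            raise ValueError("more informative bits than binary descriptors")
        if self.n_duplicate_columns > self.n_binary_descriptors:
            raise ValueError("more duplicate columns than binary descriptors")
        if not 0.0 <= self.contamination_fraction < 1.0:
            raise ValueError("contamination_fraction must be in [0, 1)")
        if self.bit_effect is not None and len(self.bit_effect) != priors.size:
            raise ValueError("bit_effect must have one entry per class")

    @property
    def n_classes(self) -> int:
        return len(self.class_priors)

    def resolved_bit_effect(self) -> np.ndarray:
        if self.bit_effect is not None:
            return np.asarray(self.bit_effect, dtype=float)
        k = self.n_classes
        return np.linspace(-0.25, 0.25, k)

    def class_names(self) -> tuple[str, ...]:
        return BINARY_CLASSES if self.n_classes == 2 else MULTICLASS5_CLASSES


def generate(spec: GeneratorSpec
             ) -> tuple[FingerprintMatrix, ActivityLabels, SourceCounts]:
    """Draw one dataset; fully deterministic for a fixed ``spec.seed``.

    Contaminant substances (the out-of-distribution block) carry random
    labels and substance ids prefixed with ``"ood-"``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_substances
    k = spec.n_classes
    labels = rng.choice(k, size=n, p=np.asarray(spec.class_priors))

    n_contam = int(round(spec.contamination_fraction * n))
    contam = np.zeros(n, dtype=bool)
    if n_contam:
        contam[n - n_contam:] = True
        labels[contam] = rng.integers(0, k, size=n_contam)

    effect = spec.resolved_bit_effect()
    nb = spec.n_binary_descriptors
    p = np.full((n, nb), 0.5)
    p[:, :spec.n_informative_bits] = np.clip(
        0.5 + effect[labels][:, None], 0.02, 0.98)
    # contaminants carry no class signal in the bits
    p[contam, :spec.n_informative_bits] = 0.5
    bits = (rng.random((n, nb)) < p).astype(float)

    nc = spec.n_continuous_descriptors
    cont = rng.standard_normal((n, nc)) + \
        spec.continuous_effect * labels[:, None]
    # out-of-distribution block: shifted far outside the training cloud
    cont[contam] += 6.0

    columns = [bits]
    ids = [f"bit{j}" for j in range(nb)]
    kinds = [BINARY] * nb
    if nc:
        columns.append(cont)
        ids += [f"prop{j}" for j in range(nc)]
        kinds += [CONTINUOUS] * nc
    if spec.n_duplicate_columns:
        columns.append(bits[:, :spec.n_duplicate_columns].copy())
        ids += [f"dup{j}" for j in range(spec.n_duplicate_columns)]
        kinds += [BINARY] * spec.n_duplicate_columns
    if spec.n_constant_columns:
        columns.append(np.zeros((n, spec.n_constant_columns)))
        ids += [f"const{j}" for j in range(spec.n_constant_columns)]
        kinds += [BINARY] * spec.n_constant_columns
    values = np.hstack(columns)

    substance_ids = [(OOD_PREFIX if contam[i] else "") + f"s{i:06d}"
                     for i in range(n)]
    dist, rate = spec.source_count_distribution
    if dist != "poisson":
        raise ValueError(f"unknown source-count distribution {dist!r}")
    sources = SourceCounts(rng.poisson(rate, size=n))
    fp = FingerprintMatrix(substance_ids, values, ids, kinds)
    lab = ActivityLabels(labels, spec.class_names(),
                         "binary" if k == 2 else "multiclass5")
    return fp, lab, sources


# priors mirroring a curated 5-class receptor-binding evaluation set
IMBALANCED5_PRIORS = (0.7448, 0.1012, 0.1320, 0.0106, 0.0114)


def benchmark_specs(seed: int = 0) -> dict[str, GeneratorSpec]:
    """The suite's named study conditions."""
    return {
        # strong planted signal: a forest should reach high test BA
        "separable": GeneratorSpec(
            n_substances=2000, n_binary_descriptors=185,
            n_continuous_descriptors=15, class_priors=(0.9, 0.1),
            n_informative_bits=25, seed=seed),
        # severe 5-class imbalance shaped like a receptor-binding dataset
        "imbalanced-5class": GeneratorSpec(
            n_substances=3000, n_binary_descriptors=120,
            n_continuous_descriptors=15, class_priors=IMBALANCED5_PRIORS,
            n_informative_bits=30,
            bit_effect=(-0.3, -0.15, 0.0, 0.15, 0.3),
            seed=seed + 1),
        # 15% out-of-distribution block with random labels
        "contaminated": GeneratorSpec(
            n_substances=1200, n_binary_descriptors=100,
            n_continuous_descriptors=15, class_priors=(0.9, 0.1),
            n_informative_bits=20, contamination_fraction=0.15,
            seed=seed + 2),
    }


def make_xor(n: int = 400, n_noise_bits: int = 8, seed: int = 0
             ) -> tuple[FingerprintMatrix, ActivityLabels, SourceCounts]:
    """Two-bit XOR labels plus noise bits: unlearnable at depth 1, easy at
    depth 2 — exercises the depth machinery."""
    rng = np.random.default_rng(seed)
    b = (rng.random((n, 2 + n_noise_bits)) < 0.5).astype(float)
    y = (b[:, 0].astype(int) ^ b[:, 1].astype(int))
    ids = [f"s{i:06d}" for i in range(n)]
    fp = FingerprintMatrix(ids, b, [f"bit{j}" for j in range(b.shape[1])],
                           [BINARY] * b.shape[1])
    return fp, ActivityLabels.binary(y), SourceCounts(rng.poisson(4.0, n))


def make_benchmark_suite(seed: int = 0) -> dict[str, tuple]:
    """Named fixtures, each a (fingerprints, labels, sources) trio.

    Expected behavior (checked by the test suite): "separable" supports
    forest test BA > 0.9; "xor" needs depth 2; "imbalanced-5class" label
    frequencies recover the priors within binomial noise; "contaminated"
    has a 15% out-of-distribution block the applicability domain should
    mostly exclude.
    """
    suite = {name: generate(s) for name, s in benchmark_specs(seed).items()}
    suite["xor"] = make_xor(seed=seed + 3)
    return suite
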