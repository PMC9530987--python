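"""Genetic-algorithm post-optimization of a trained forest.

The chromosome is exactly the mutable part of a :class:`ForestModel`: one
(enabled, depth_cap) gene per tree.  Trees are never retrained — capping is a
prediction-time operation — so the GA explores the space of sub-ensembles of
the trained forest.

The fitness rewards balanced accuracy on both the training and the held-out
test split while penalizing the gap between them (an overfit ensemble has a
large gap):

    F = (BA_train + BA_test) / 2 - lambda * |BA_train - BA_test|

with ``lambda = 0.5`` by default (``lambda = 0`` recovers the plain mean).
The exact scoring used by the original screening workflow is not published;
this default is the package's documented stand-in and is fully configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core_data import ActivityLabels, FingerprintMatrix
from .decision_tree import predict_tree_batch
from .metrics import balanced_accuracy, confusion
from .random_forest import ForestModel


@dataclass
class Chromosome:
    enabled: np.ndarray    # per-tree bool
    depth_cap: np.ndarray  # per-tree int, in [0, tree_depth]

    def __post_init__(self) -> None:
        self.enabled = np.asarray(self.enabled, dtype=bool)
        self.depth_cap = np.asarray(self.depth_cap, dtype=int)
        if self.enabled.shape != self.depth_cap.shape:
            raise ValueError("enabled and depth_cap lengths differ")

    def copy(self) -> "Chromosome":
        return Chromosome(self.enabled.copy(), self.depth_cap.copy())


@dataclass
class GAConfig:
    population_size: int = 50
    n_generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    elitism_count: int = 2
    tournament_size: int = 3
    overfit_penalty: float = 0.5  # lambda; 0 -> plain mean of the two BAs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.elitism_count < 1:
            raise ValueError("elitism_count must be >= 1")


def identity_chromosome(model: ForestModel) -> Chromosome:
    """All trees enabled at their full depth — the unoptimized forest."""
    depths = np.array([t.depth() for t in model.trees], dtype=int)
    return Chromosome(np.ones(model.n_trees, dtype=bool), depths)


def apply_chromosome(model: ForestModel, chrom: Chromosome) -> ForestModel:
    """Forest with the chromosome's enabled flags and depth caps applied.
    The trees themselves are untouched (caps act at prediction time)."""
    if chrom.enabled.size != model.n_trees:
        raise ValueError("chromosome length does not match forest")
    if not chrom.enabled.any():
        raise ValueError("chromosome disables every tree")
    return replace(model, enabled=chrom.enabled.copy(),
                   depth_cap=[int(c) for c in chrom.depth_cap])


class ChromosomeEvaluator:
    """Precomputes every tree's prediction at every depth cap on both splits,
    making per-chromosome fitness a cheap table lookup plus a vote."""

    def __init__(self, model: ForestModel,
                 fp_train: FingerprintMatrix, labels_train: ActivityLabels,
                 fp_test: FingerprintMatrix, labels_test: ActivityLabels):
        self.model = model
        self.k = model.n_classes
        self.depths = np.array([t.depth() for t in model.trees], dtype=int)
        self.y_train = labels_train
        self.y_test = labels_test
        self._train = self._precompute(fp_train.values)
        self._test = self._precompute(fp_test.values)

    def _precompute(self, X: np.ndarray) -> list[np.ndarray]:
        tables = []
        for tree, depth in zip(self.model.trees, self.depths):
            table = np.empty((depth + 1, X.shape[0]), dtype=np.int64)
            for cap in range(depth + 1):
                table[cap] = predict_tree_batch(tree, X, cap if cap < depth else None)
            tables.append(table)
        return tables

    def _vote(self, tables: list[np.ndarray], chrom: Chromosome) -> np.ndarray:
        n = tables[0].shape[1]
        tallies = np.zeros((n, self.k), dtype=np.int64)
        rows = np.arange(n)
        for i, table in enumerate(tables):
            if not chrom.enabled[i]:
                continue
            cap = min(int(chrom.depth_cap[i]), table.shape[0] - 1)
            tallies[rows, table[cap]] += 1
        return (self.k - 1 - np.argmax(tallies[:, ::-1], axis=1)).astype(int)

    def fitness(self, chrom: Chromosome, overfit_penalty: float = 0.5) -> float:
        if not chrom.enabled.any():
            return -math.inf
        ba_train = balanced_accuracy(
            confusion(self.y_train, self._vote(self._train, chrom)),
            ignore_empty=True)
        ba_test = balanced_accuracy(
            confusion(self.y_test, self._vote(self._test, chrom)),
            ignore_empty=True)
        return (ba_train + ba_test) / 2.0 \
            - overfit_penalty * abs(ba_train - ba_test)


def fitness(model: ForestModel, chrom: Chromosome,
            fp_train: FingerprintMatrix, labels_train: ActivityLabels,
            fp_test: FingerprintMatrix, labels_test: ActivityLabels,
            overfit_penalty: float = 0.5) -> float:
    """Fitness of one chromosome (see module docstring for the formula)."""
    if not chrom.enabled.any():
        return -math.inf
    ev = ChromosomeEvaluator(model, fp_train, labels_train, fp_test, labels_test)
    return ev.fitness(chrom, overfit_penalty)


def _random_chromosome(depths: np.ndarray, rng: np.random.Generator) -> Chromosome:
    enabled = rng.random(depths.size) < 0.8
    if not enabled.any():
        enabled[rng.integers(depths.size)] = True
    caps = np.array([rng.integers(0, d + 1) for d in depths], dtype=int)
    return Chromosome(enabled, caps)


def _mutate(chrom: Chromosome, depths: np.ndarray, rate: float,
            rng: np.random.Generator) -> Chromosome:
    c = chrom.copy()
    for i in range(depths.size):
        if rng.random() < rate:
            if rng.random() < 0.5:
                c.enabled[i] = not c.enabled[i]
            else:
                step = 1 if rng.random() < 0.5 else -1
                c.depth_cap[i] = int(np.clip(c.depth_cap[i] + step, 0, depths[i]))
    if not c.enabled.any():
        c.enabled[rng.integers(depths.size)] = True
    return c


def _crossover(a: Chromosome, b: Chromosome,
               rng: np.random.Generator) -> Chromosome:
    take_b = rng.random(a.enabled.size) < 0.5
    enabled = np.where(take_b, b.enabled, a.enabled)
    caps = np.where(take_b, b.depth_cap, a.depth_cap)
    if not enabled.any():
        enabled = enabled.copy()
        enabled[rng.integers(enabled.size)] = True
    return Chromosome(enabled, caps)


def evolve(model: ForestModel,
           fp_train: FingerprintMatrix, labels_train: ActivityLabels,
           fp_test: FingerprintMatrix, labels_test: ActivityLabels,
           config: GAConfig | None = None) -> tuple[Chromosome, list[float]]:
    """Evolve (enabled, depth_cap) genes; returns the best-ever chromosome and
    the per-generation best-fitness history (monotone by elitism).

    The identity chromosome is always seeded into generation 0, so the result
    can never be worse than the unoptimized forest.
    """
    if config is None:
        config = GAConfig()
    rng = np.random.default_rng(config.seed)
    ev = ChromosomeEvaluator(model, fp_train, labels_train, fp_test, labels_test)
    depths = ev.depths
    lam = config.overfit_penalty

    pop = [identity_chromosome(model)]
    while len(pop) < config.population_size:
        pop.append(_random_chromosome(depths, rng))
    scores = [ev.fitness(c, lam) for c in pop]
    best_i = int(np.argmax(scores))
    best, best_score = pop[best_i].copy(), scores[best_i]
    history = [best_score]
    if config.n_generations == 0:
        return pop[0], [scores[0]]

    def tournament() -> Chromosome:
        idx = rng.integers(0, len(pop), size=config.tournament_size)
        return pop[idx[int(np.argmax([scores[i] for i in idx]))]]

    for _ in range(config.n_generations):
        order = np.argsort(scores)[::-1]
        new_pop = [pop[i].copy() for i in order[:config.elitism_count]]
        while len(new_pop) < config.population_size:
            parent = tournament()
            child = _crossover(parent, tournament(), rng) \
                if rng.random() < config.crossover_rate else parent.copy()
            new_pop.append(_mutate(child, depths, config.mutation_rate, rng))
        pop = new_pop
        scores = [ev.fitness(c, lam) for c in pop]
        gen_best = int(np.argmax(scores))
        if scores[gen_best] > best_score:
            best, best_score = pop[gen_best].copy(), scores[gen_best]
        history.append(best_score)
    return best, history
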