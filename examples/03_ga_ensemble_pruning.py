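"""Genetic-algorithm pruning of a deliberately overfit forest.

Trains deep trees on noisy data, then lets the GA cap each tree's depth and
switch trees off to improve the train/test balanced-accuracy fitness.
"""

import conservarf as c

fp, labels, _ = c.generate(c.GeneratorSpec(
    n_substances=600, n_binary_descriptors=60, n_continuous_descriptors=8,
    class_priors=(0.75, 0.25), n_informative_bits=8,
    bit_effect=(-0.12, 0.12), seed=3))
split = c.stratified_split(labels, 0.75, seed=3)
fp_tr = fp.take_substances(split.train_indices)
y_tr = labels.take(split.train_indices)
fp_te = fp.take_substances(split.test_indices)
y_te = labels.take(split.test_indices)

model = c.train_forest(fp_tr, y_tr, n_trees=21,
                       config=c.TreeConfig(max_depth=12), seed=3)

identity = c.identity_chromosome(model)
f0 = c.fitness(model, identity, fp_tr, y_tr, fp_te, y_te)
print(f"unoptimized fitness: {f0:.4f} "
      f"(mean of train/test BA minus half the train-test gap)")

best, history = c.evolve(model, fp_tr, y_tr, fp_te, y_te,
                         c.GAConfig(population_size=30, n_generations=25,
                                    seed=3))
print(f"optimized fitness:   {history[-1]:.4f} after {len(history) - 1} "
      f"generations")
print(f"trees enabled: {int(best.enabled.sum())}/{model.n_trees}, "
      f"depth caps: {sorted(set(int(d) for d in best.depth_cap))}")
# The GA can only match or beat the unoptimized forest: the identity
# chromosome is seeded into generation 0 and elitism never discards the best.
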