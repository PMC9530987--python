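"""The full training protocol in one call.

Runs dedup-free: split -> prune -> train one forest per cost function ->
GA-optimize each -> pick the representative by fitness -> fit the
applicability domain -> evaluate, writing all artifacts to ./protocol_run/.

The same protocol is available from the shell:
    conservarf run --config cfg.json --seed 5
"""

import conservarf as c
from conservarf.ga_optimizer import GAConfig
from conservarf.protocol import RunConfig, run_protocol

data = c.generate(c.GeneratorSpec(
    n_substances=800, n_binary_descriptors=80, n_continuous_descriptors=10,
    class_priors=(0.85, 0.15), n_informative_bits=15,
    n_duplicate_columns=2, n_constant_columns=2, seed=5))

config = RunConfig(
    out_dir="protocol_run", seed=5,
    costs=("gini", "balanced_accuracy", "mcc", "macro_f"),
    n_trees=31, max_depth=10,
    ga=GAConfig(population_size=20, n_generations=15, seed=5),
)
result = run_protocol(config, data)

print(f"cost functions tried: {list(result.fitness_by_cost)}")
for cost, f in sorted(result.fitness_by_cost.items(), key=lambda kv: -kv[1]):
    marker = " <- representative" if cost == result.cost_chosen else ""
    print(f"  {cost}: fitness {f:.4f}{marker}")
print(f"descriptors kept after pruning: {len(result.keep_list)}")
print(f"AD looseness m = {result.m_chosen}")
test = result.metrics["test_all"]
print(f"test balanced accuracy: {100 * test['balanced_accuracy']:.1f}%  "
      f"coverage: {100 * test['coverage']:.1f}%")
# One forest is trained per split-cost; the GA-optimized forest with the
# best train/test fitness becomes the representative model, exactly one per
# receptor/activity/classifier combination in a production screen.
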