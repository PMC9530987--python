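# Methods

This note documents the models and procedures implemented in `conservarf`,
the parameters that matter, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## The classification problem

Receptor-activity datasets for screening are large, mostly binary-featured
and severely imbalanced: a few hundred Active substances against several
thousand Inactive ones, optionally refined into an ordered potency scale
Inactive < Very Weak < Weak < Moderate < Strong. Two design commitments
follow. First, every summary statistic must be robust to imbalance, which
is why balanced accuracy (mean per-class recall) is the primary metric: its
floor is 1/n_classes for any constant predictor, not the majority
prevalence. Second, the cost of errors is asymmetric — the models feed a
priority-setting tier where missing an active substance is worse than
flagging an inactive one — so every tie-break in the system prefers the
stronger activity class.

## Decision trees

Trees are binary-test CART-style trees with three non-standard elements.

*Per-tree equal-width binning.* Before a tree is grown, every continuous
descriptor is binned into 20 equal-width bins over the *tree's own sample*
range; the 19 internal boundaries are the only candidate thresholds. A
molar-mass range of 50–250 yields candidates 60, 70, …, 240. Because each
tree samples different substances, each tree sees slightly different
boundaries, adding diversity. Binning happens once per tree, not per node.

*Pluggable split costs.* A candidate split is scored either by the weighted
mean of child Gini impurities (lower better) or by a classification metric
(balanced accuracy, multi-class Matthews correlation, macro F) of the
labeling that assigns every sample its child's conservative-majority class
(higher better); all costs are internally oriented to higher-is-better and
a split is accepted only if it strictly improves on the unsplit node. The
metric costs average over the classes present at the node; classes with
undefined contributions score zero. One consequence worth knowing: under
the two-child majority labeling, a balanced-accuracy or macro-F gain
requires a child whose majority actually flips, so on heavily imbalanced
nodes these costs can refuse to split and produce stumps. The protocol
trains one forest per requested cost and picks the best by fitness, which
in practice usually selects the Gini forest on strongly imbalanced data —
the metric costs are kept because they can win on more balanced, multi-class
problems.

*Conservative leaves and depth caps.* Every node, internal or leaf, stores
its class-count vector. Prediction routes a query until a leaf *or* an
externally supplied depth cap and returns the stop node's conservative
majority (ties to the higher class index). Storing counts everywhere is
what makes post-hoc depth capping a pure prediction-time operation.

Defaults: `max_depth` 20, `min_node_size` 2, feature subset ⌈√d⌉ drawn
fresh per node without replacement, candidate ties broken by (lowest
descriptor index, lowest threshold) for reproducibility.

## Forests

101 trees by default, each trained on an independent random 75% subset of
the training substances drawn *without* replacement (subsets, not
bootstrap). Per-tree RNG streams derive from `(seed, tree_index)`, so
training is reproducible and tree i is identical whether 3 or 101 trees are
requested. Forest prediction tallies the enabled trees' votes and applies
the conservative rule: maximum tally, ties to the strongest class. There is
no out-of-bag machinery; assessment uses the held-out stratified 25% test
split. The 75/25 split is stratified per class (floor rounding, singleton
classes go to train with a warning) because rare potency classes — tens of
Strong binders in a several-thousand-substance dataset — would otherwise
risk vanishing from train or test entirely.

## Genetic-algorithm ensemble optimization

The chromosome has one gene per tree: an enabled flag and a depth cap in
[0, tree depth]. Fitness is

    F = (BA_train + BA_test)/2 − λ·|BA_train − BA_test|,  λ = 0.5,

computed on conservative forest predictions under the chromosome. The
penalty term targets the overfitting signature (large train/test gap);
λ = 0 recovers the plain mean. This formula is the package's own documented
scoring — it is configurable precisely because it is a design choice rather
than a community standard. The GA is generational with tournament selection
(size 3), uniform per-gene crossover (rate 0.8), per-gene mutation (rate
0.05; a mutation flips the enabled bit or steps the cap ±1, clipped), and
elitism (2). The identity chromosome (all trees enabled, uncapped) is
seeded into generation 0, so the optimized forest can never be worse than
the unoptimized one, and best-ever fitness is monotone across generations.
Fitness evaluation precomputes every tree's prediction at every depth cap
once, making a chromosome evaluation a table lookup plus a vote.

## Applicability domain

The domain is a density k-nearest-neighbour construction on a PCA
embedding. PCA is fitted on the pruned *training* fingerprints only,
keeping the smallest number of components whose cumulative explained
variance reaches 95%; component signs are fixed (largest-magnitude loading
positive) so embeddings are deterministic. Each embedded training point
gets a raw admission radius equal to the mean Euclidean distance to its
k = 5 nearest training neighbours. The n^(1/m) rule supplies a global cap:
with n training points, the cap is the ⌈n^(1/m)⌉-th largest raw radius, and
every radius is clipped to it. The cap trims the inflated radii of isolated
training points — exactly the points whose neighbourhoods should not count
as dense chemical space. Under this reading, small m clips aggressively
(m = 1 clips every radius to the minimum; tightest domain) and large m
barely clips (loosest); m is therefore a looseness dial scanned over a grid
(default 1.0–10.0 in steps of 0.5). A query is in-domain iff it lies within
the clipped radius of at least one training point.

`optimize_m` evaluates, for each grid value, the coverage and the in-domain
balanced accuracy of the model on an evaluation set, and returns the m
maximizing BA subject to coverage ≥ 0.85 (roughly "remove at most 15% of
the data"); when no grid value meets the floor it falls back to the
highest-coverage BA-improving value. In-domain BA averages recalls over the
classes actually present in the domain, since a rare class can be excluded
entirely.

What n^(1/m) thresholds is deliberately a documented interpretation: the
expression is stated in the underlying methodology without pinning down the
quantity it cuts, and the quantile-of-radii reading was chosen because it
keeps the threshold dimensionless and data-scaled. Alternative rules can be
swapped in by constructing `ADModel` radii differently.

## Descriptor handling

Fingerprint assembly is an adapter contract: anything mapping a structure
string to a fixed-width numeric vector with declared binary/continuous
kinds can be concatenated, with descriptor ids prefixed by generator name.
A substance failing any adapter is dropped with a logged warning, never
zero-filled. The bundled `RandomProjectionAdapter` is a hash-based
stand-in — chemically meaningless, structurally faithful — so assembly is
testable without external fingerprint software; computing real PubChem /
MACCS / FP2-4 bits is explicitly outside this package.

Pruning is two ordered steps fitted on training data only: remove
zero-variance columns, then scan columns left-to-right and drop any with
|Pearson r| > 0.98 against an already-kept column (the earlier column
survives; anti-correlated bits are treated as redundant by default, with a
signed-r option for literal fidelity). The learned keep-list is applied to
test and new data. Pruning is deterministic and idempotent.

Curation utilities: exact-string duplicate removal keeping first occurrence
(conflicting duplicate labels resolve to the strongest — the conservative
choice), and a ≥k-sources filter (k = 4 in the motivating workflow).

## Synthetic data

The generator emulates the statistical shape of curated receptor-activity
data: labels drawn from explicit priors (e.g. 94.5%/5.5% binary, or the
5-class prior vector 0.745/0.101/0.132/0.011/0.011 used by the
`imbalanced-5class` benchmark); informative bits Bernoulli with per-class
probability shifts around 0.5; uninformative bits Bernoulli(0.5); 15
continuous descriptors as class-shifted unit Gaussians; optional exact
duplicate columns, all-zero constant columns, and an out-of-distribution
contaminant block (continuous means shifted +6σ, no bit signal, random
labels, substance ids prefixed `ood-`); Poisson(4) source counts. Defaults
(2000 substances, 185 binary + 15 continuous descriptors, 25 informative
bits at ±0.25) define the `separable` benchmark on which a default forest
reaches test BA > 0.9.

What passing on this data shows: the split search, conservative voting, GA
and AD behave as specified, signal that is present is found, and absent
signal (label permutation) yields chance-level BA. What it does not show:
performance on real chemistry — real fingerprints are sparse, blockwise
correlated and tied to structural neighbourhoods in ways independent
Bernoulli bits are not, and real potency classes are not generated by
monotone per-bit probability shifts.

## Numerical and testing choices

Split acceptance uses a strict-improvement epsilon of 1e-12; vote and
majority ties always resolve upward; model JSON round-trips bit-exactly
(trees, enabled flags, caps, AD). Test problem sizes were chosen so the
whole suite exercises the full 101-tree, 2000-substance condition exactly
once (shared fixture) and uses 3–31-tree forests elsewhere; the GA
global-optimality check enumerates the complete chromosome space of a
3-tree forest. The acceptance script's supporting quantities (planted-signal
test BA, AD coverage) are stochastic by design and reported to one decimal.

## Known limitations

- The GA fitness is a stand-in for an unpublished scoring; conclusions
  about the *exact* original optimization do not transfer.
- Metric-based split costs can under-split extremely imbalanced nodes (see
  above); they are offered as alternatives, not the recommended default.
- The n^(1/m) admission rule is one defensible reading of an
  underspecified threshold; the m grid scan makes results robust to the
  reading's direction, but absolute m values are not comparable across
  implementations.
- No probability calibration, vote weighting, cost-complexity pruning or
  missing-value routing; loaders reject missing values by default and can
  impute continuous medians only.
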