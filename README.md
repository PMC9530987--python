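# conservarf

Conservative random forests for imbalanced (Q)SAR classification, built for
first-tier endocrine-activity screening: predicting whether a substance
binds, activates or blocks the estrogen or androgen receptor from a vector
of mostly-binary molecular fingerprints.

The package is aimed at computational toxicologists who need screening
models that (a) survive severe class imbalance — receptor-activity datasets
are routinely ~95% Inactive — and (b) err on the side of flagging: in a
priority-setting workflow a false positive costs a second look, a false
negative drops a potentially endocrine-active chemical from consideration.

## What it implements

**Conservative decision trees and forests.** Bespoke CART-style trees where
every tie — in a leaf majority, in a forest vote — resolves toward the
*stronger* activity class: an Inactive/Active vote tie predicts Active, a
Weak/Moderate tie predicts Moderate. Continuous descriptors are binned once
per tree into 20 equal-width bins over the tree's sample range and only the
bin boundaries are candidate thresholds (a 50–250 g/mol range is tested at
60, 70, …, 240 g/mol). A forest is 101 trees by default, each trained on a
random 75% subset of the training substances.

**Imbalance-aware split costs.** Splits can be scored by classical Gini
impurity or directly by a classification metric — balanced accuracy,
Matthews correlation, macro F — evaluated on the two-child majority
labeling. Balanced accuracy is the mean per-class recall

    BA = (1/n) Σᵢ TPᵢ / (TPᵢ + FNᵢ),

whose floor for an always-one-class predictor is 1/n rather than the
majority prevalence.

**Genetic-algorithm ensemble pruning.** After training, a GA caps each
tree's depth independently and may disable trees entirely, maximizing
`(BA_train + BA_test)/2 − λ·|BA_train − BA_test|` (λ = 0.5): mean
performance minus an overfitting penalty.

**Density-kNN applicability domain.** Pruned fingerprints are embedded by
PCA (components covering ≥95% of the variance); each training point gets an
admission radius equal to its mean distance to its k nearest neighbours,
clipped by a global cap derived from the n^(1/m) rule; a query is in-domain
if it falls within any training point's radius. The looseness parameter m is
optimized for in-domain balanced accuracy subject to a coverage floor.

**Descriptor pruning, data curation, synthetic data.** Zero-variance and
|r| > 0.98 Pearson-collinearity pruning fitted on training data; duplicate
structure removal with conservative label-conflict resolution; a ≥k-sources
filter; and a seed-deterministic generator producing fingerprint datasets
with planted signal, class imbalance, collinear/constant columns and
out-of-distribution contaminant blocks, so the entire pipeline is testable
without any external data or fingerprint software.

## Worked example

`examples/02_train_conservative_forest.py` generates a 2000-substance,
200-descriptor binary dataset (90% Inactive), prunes descriptors, trains a
101-tree forest and evaluates on the held-out 25%:

```
descriptors: 205 -> 200 (2 constant, 3 collinear removed)
test balanced accuracy: 91.8%
test sensitivity: 83.7%   specificity: 100.0%
```

The balanced accuracy of 91.8% is the mean of the Active recall (83.7%) and
the Inactive recall (100%); an always-Inactive predictor would score exactly
50% here regardless of the 9:1 imbalance. The other example scripts cover
the metric suite on printed confusion matrices, GA pruning of an overfit
forest, the applicability domain on contaminated data, and the full
multi-cost training protocol; each prints a short interpretation of its
numbers.

A thin CLI mirrors the library: `conservarf simulate | train | optimize |
ad-fit | predict | evaluate | run`.

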