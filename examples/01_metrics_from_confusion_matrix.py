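"""Evaluation metrics from confusion matrices of an endocrine-activity model.

Builds the kind of confusion matrices a receptor-activity screen produces —
a binary Inactive/Active matrix with severe imbalance and a 5-class potency
matrix — and derives every reported statistic from them.
"""

import numpy as np

from conservarf.metrics import (ConfusionMatrix, balanced_accuracy,
                                binary_stats, macro_f, mcc, per_class_recall)

# Binary screen: 5,051 observed Inactive vs 350 observed Active substances.
binary_cm = ConfusionMatrix(np.array([[4444, 607],
                                      [42, 308]]), ("Inactive", "Active"))
stats = binary_stats(binary_cm)
print("binary screen")
print(f"  balanced accuracy: {100 * balanced_accuracy(binary_cm):.1f}%")
print(f"  sensitivity: {100 * stats['sensitivity']:.1f}%   "
      f"specificity: {100 * stats['specificity']:.1f}%")
print(f"  precision: {100 * stats['precision']:.1f}%")

# Balanced accuracy stays high while precision is low: with ~14x more
# Inactive substances, even a 12% false-positive rate swamps the true
# actives.  For a conservative first-tier screen that trade is intended —
# false negatives are the costly error.

five_class_cm = ConfusionMatrix(np.array([
    [3416, 854, 73, 128, 113],
    [3, 35, 0, 2, 0],
    [23, 72, 67, 22, 5],
    [0, 1, 0, 24, 5],
    [0, 0, 0, 5, 25],
]), ("Inactive", "Very Weak", "Weak", "Moderate", "Strong"))
print("5-class potency screen")
recalls = per_class_recall(five_class_cm)
for name, r in zip(five_class_cm.class_names, recalls):
    print(f"  recall[{name}]: {100 * r:.1f}%")
print(f"  balanced accuracy (mean recall): "
      f"{100 * balanced_accuracy(five_class_cm):.1f}%")
print(f"  multi-class MCC: {mcc(five_class_cm):.3f}   "
      f"macro F1: {macro_f(five_class_cm):.3f}")
# An always-Inactive predictor would score exactly 1/5 = 20% balanced
# accuracy here, so 72% reflects genuine multi-class skill.
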