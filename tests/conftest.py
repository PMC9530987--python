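import numpy as np
import pytest

from conservarf.core_data import BINARY_CLASSES, MULTICLASS5_CLASSES
from conservarf.metrics import ConfusionMatrix


@pytest.fixture(scope="session")
def er_antagonist_cm() -> ConfusionMatrix:
    """Published binary confusion matrix of an ER screening model on a
    >=4-sources evaluation set: 5,051 observed Inactive, 350 observed
    Active."""
    return ConfusionMatrix(np.array([[4444, 607], [42, 308]]), BINARY_CLASSES)


@pytest.fixture(scope="session")
def multiclass_binding_cm() -> ConfusionMatrix:
    """Published 5-class binding-potency confusion matrix
    (Inactive..Strong)."""
    counts = np.array([
        [3416, 854, 73, 128, 113],
        [3, 35, 0, 2, 0],
        [23, 72, 67, 22, 5],
        [0, 1, 0, 24, 5],
        [0, 0, 0, 5, 25],
    ])
    return ConfusionMatrix(counts, MULTICLASS5_CLASSES)


@pytest.fixture(scope="session")
def separable_dataset():
    """Planted-signal synthetic dataset at the suite's study conditions
    (2000 substances x 200 descriptors, 10% Active), with its 75/25 split."""
    import conservarf as c

    fp, labels, sources = c.generate(c.GeneratorSpec(seed=7))
    split = c.stratified_split(labels, 0.75, seed=7)
    return fp, labels, sources, split


@pytest.fixture(scope="session")
def separable_forest(separable_dataset):
    """A 101-tree Gini forest trained on the separable dataset's train split."""
    import conservarf as c

    fp, labels, _, split = separable_dataset
    fp_train = fp.take_substances(split.train_indices)
    y_train = labels.take(split.train_indices)
    return c.train_forest(fp_train, y_train, n_trees=101, seed=7)


@pytest.fixture
def tiny_binary_fp():
    """6 substances x 3 binary bits; bit0 perfectly separates the classes."""
    from conservarf.core_data import BINARY, ActivityLabels, FingerprintMatrix

    values = np.array([
        [0, 1, 0],
        [0, 0, 1],
        [0, 1, 1],
        [1, 0, 0],
        [1, 1, 0],
        [1, 0, 1],
    ], dtype=float)
    fp = FingerprintMatrix([f"s{i}" for i in range(6)], values,
                           ["b0", "b1", "b2"], [BINARY] * 3)
    labels = ActivityLabels.binary([0, 0, 0, 1, 1, 1])
    return fp, labels
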