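import numpy as np
import pytest

from dualks import ClassVector, ExpressionMatrix, class_mean_example, worked_example


@pytest.fixture
def worked():
    """The 1-gene, 8-sample, 3-class hand-checkable example."""
    return worked_example()


@pytest.fixture
def mean_example():
    """The 3x3 class-mean matrix used for the weighting example."""
    return class_mean_example()


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def make_dataset(rng, n_genes=20, n_per_class=4, classes=("A", "B", "C")):
    """Small random matrix with distinct values (continuous noise)."""
    n = n_per_class * len(classes)
    values = rng.normal(size=(n_genes, n))
    gene_ids = [f"g{i:03d}" for i in range(n_genes)]
    sample_ids = [f"s{j:03d}" for j in range(n)]
    labels = np.repeat(list(classes), n_per_class)
    X = ExpressionMatrix(values, gene_ids, sample_ids)
    Y = ClassVector.from_labels(labels, classes=list(classes))
    return X, Y
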