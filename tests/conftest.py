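import numpy as np
import pytest

from rfacogs.dataio import ExpressionDataset


def make_dataset(values, labels, gene_ids=None):
    """Build a small ExpressionDataset from raw arrays for tests."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    gene_ids = gene_ids or tuple(f"g{j + 1}" for j in range(p))
    sample_ids = tuple(f"s{i + 1}" for i in range(n))
    return ExpressionDataset(values, tuple(gene_ids), sample_ids, tuple(labels))


def random_dataset(rng, n_samples, n_genes, n_classes=2):
    """A random labeled dataset with every class represented at least twice."""
    values = rng.normal(size=(n_samples, n_genes))
    labels = [f"C{i % n_classes}" for i in range(n_samples)]
    labels = [labels[i] for i in rng.permutation(n_samples)]
    return make_dataset(values, labels)


@pytest.fixture
def two_class_separable():
    """Two tight, well-separated point clouds: 1-NN must be perfect."""
    rng = np.random.default_rng(7)
    a = rng.normal(0.0, 0.1, size=(10, 3))
    b = rng.normal(10.0, 0.1, size=(10, 3))
    values = np.vstack([a, b])
    labels = ["A"] * 10 + ["B"] * 10
    return make_dataset(values, labels)
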