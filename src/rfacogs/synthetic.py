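"""Seeded synthetic expression data with known ground truth.

Emulates the small-n / large-p regime of microarray tumor studies: tens
to hundreds of samples, hundreds to thousands of genes, of which a small
planted set is class-informative, a further set is a redundant (noisy
copy) of the informative set, and the rest is class-independent noise.

The class-conditional model is Gaussian: an informative gene's mean in
class ``c`` is ``c * effect_size * noise_sd`` (adjacent classes are
separated by ``effect_size`` within-class standard deviations) with
within-class noise ``noise_sd``; a redundant gene is its parent
informative gene plus independent ``N(0, redundancy_noise_sd)`` noise;
null genes are ``N(0, noise_sd)`` regardless of class. Ground-truth
columns are shuffled into random positions so positional assumptions
cannot pass recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import ExpressionDataset

__all__ = ["SyntheticSpec", "GroundTruth", "generate"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``effect_size`` is the class-mean separation of informative genes in
    units of the within-class standard deviation ``noise_sd``.
    """

    n_samples: int = 100
    n_genes: int = 500
    n_classes: int = 2
    n_informative: int = 10
    n_redundant: int = 10
    effect_size: float = 1.5
    noise_sd: float = 1.0
    redundancy_noise_sd: float = 1.0
    class_proportions: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2 or self.n_genes < 1 or self.n_classes < 2:
            raise ValueError("need n_samples >= 2, n_genes >= 1, n_classes >= 2")
        if self.n_informative < 0 or self.n_redundant < 0:
            raise ValueError("gene role counts must be non-negative")
        if self.n_informative + self.n_redundant > self.n_genes:
            raise ValueError("n_informative + n_redundant exceeds n_genes")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ValueError("redundant genes need informative parents")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0 or self.redundancy_noise_sd <= 0:
            raise ValueError("noise standard deviations must be positive")
        props = self.class_proportions or tuple(
            1.0 / self.n_classes for _ in range(self.n_classes)
        )
        props = tuple(float(p) for p in props)
        if len(props) != self.n_classes:
            raise ValueError("class_proportions length must equal n_classes")
        if any(p <= 0 for p in props) or abs(sum(props) - 1.0) > 1e-12:
            raise ValueError("class_proportions must be positive and sum to 1")
        object.__setattr__(self, "class_proportions", props)
        if self.n_samples < self.n_classes:
            raise ValueError("need at least one sample per class")


@dataclass(frozen=True)
class GroundTruth:
    """Planted gene roles as dataset column indices."""

    informative: np.ndarray
    redundant: np.ndarray
    redundant_parent: dict  # redundant column -> informative parent column

    def role_of(self, gene_index: int) -> str:
        if gene_index in set(self.informative.tolist()):
            return "informative"
        if gene_index in set(self.redundant.tolist()):
            return "redundant"
        return "null"


def _class_counts(spec: SyntheticSpec) -> np.ndarray:
    """Largest-remainder apportionment of samples to classes, >= 1 each."""
    raw = np.asarray(spec.class_proportions) * spec.n_samples
    counts = np.floor(raw).astype(int)
    counts = np.maximum(counts, 1)
    while counts.sum() > spec.n_samples:
        counts[np.argmax(counts)] -= 1
    remainder = raw - np.floor(raw)
    while counts.sum() < spec.n_samples:
        order = np.lexsort((np.arange(counts.size), -remainder))
        counts[order[0]] += 1
        remainder[order[0]] = -1
    return counts


def generate(spec: SyntheticSpec):
    """Generate one dataset; returns ``(ExpressionDataset, GroundTruth)``.

    Fully determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _class_counts(spec)
    labels = np.repeat([f"C{c}" for c in range(spec.n_classes)], counts)
    labels = labels[rng.permutation(spec.n_samples)]
    class_codes = np.array([int(l[1:]) for l in labels])

    n, p = spec.n_samples, spec.n_genes
    n_inf, n_red = spec.n_informative, spec.n_redundant
    values = np.empty((n, p))

    # informative block: class-specific means, within-class gaussian noise
    class_means = np.arange(spec.n_classes) * spec.effect_size * spec.noise_sd
    inf_block = (class_means[class_codes][:, None]
                 + rng.normal(0.0, spec.noise_sd, size=(n, n_inf)))
    values[:, :n_inf] = inf_block

    # redundant block: round-robin parents plus independent noise
    parents = np.arange(n_red) % max(n_inf, 1)
    red_block = (inf_block[:, parents]
                 + rng.normal(0.0, spec.redundancy_noise_sd, size=(n, n_red)))
    values[:, n_inf:n_inf + n_red] = red_block

    # null block: class-independent noise
    n_null = p - n_inf - n_red
    values[:, n_inf + n_red:] = rng.normal(0.0, spec.noise_sd, size=(n, n_null))

    # shuffle gene columns so planted roles land in random positions
    perm = rng.permutation(p)
    values = values[:, perm]
    position = np.empty(p, dtype=int)
    position[perm] = np.arange(p)  # original block index -> final column

    informative = np.sort(position[:n_inf])
    redundant = np.sort(position[n_inf:n_inf + n_red])
    parent_map = {
        int(position[n_inf + j]): int(position[parents[j]]) for j in range(n_red)
    }

    gene_ids = tuple(f"g{i + 1:04d}" for i in range(p))
    sample_ids = tuple(f"s{i + 1}" for i in range(n))
    dataset = ExpressionDataset(values, gene_ids, sample_ids, tuple(labels))
    truth = GroundTruth(informative=informative, redundant=redundant,
                        redundant_parent=parent_map)
    return dataset, truth
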