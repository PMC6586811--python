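"""ReliefF-family gene weighting: the filter stage.

Relief-type algorithms score a gene by how well it separates a sample
from its nearest *misses* (nearest neighbors in other classes) relative
to its nearest *hits* (nearest neighbors in its own class): a gene that
varies little among hits but a lot toward misses is class-informative.

Two weight-update rules are implemented over identical sampling,
neighbor-search and tie-breaking machinery so that their difference
isolates the formula change:

``classic_relieff_weights``
    The standard multiclass ReliefF update: for each of ``m`` randomly
    drawn samples, subtract the range-normalized per-neighbor hit
    differences and add the prior-weighted per-neighbor miss
    differences, everything divided by ``m * k``.

``improved_relieff_weights``
    A centroid variant: per gene, the hit (miss) contribution is the
    distance of the drawn sample to the *mean* of its k hit (miss)
    neighbors rather than a per-neighbor sum, multiplied by the realized
    neighbor count so its magnitude matches the classic per-neighbor
    sum; and each contribution is scaled by a *distance coefficient* —
    the dispersion (population standard deviation over absolute sum) of
    the Euclidean distances from the drawn sample to those neighbors —
    which damps updates from draws whose neighborhoods are erratic and
    stabilizes the weights across repeats.

Determinism contract: the ``m`` sample draws are
``numpy.random.default_rng(seed).integers(0, n_samples, size=m)``
(sampling with replacement); identical ``(dataset, m, k, seed)`` give
bitwise-identical weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import ExpressionDataset

__all__ = [
    "NeighborContext",
    "GeneWeightVector",
    "euclidean_distance",
    "find_neighbors",
    "same_class_distance",
    "diff_class_distance",
    "distance_coefficient",
    "improved_relieff_weights",
    "classic_relieff_weights",
    "filter_top_genes",
    "draw_sample_indices",
]


@dataclass(frozen=True)
class NeighborContext:
    """Hit/miss neighborhoods of one target sample.

    ``same_class_neighbors`` is empty when the target is the only member
    of its class; callers must then skip the within-class term.
    ``diff_class_neighbors`` maps every *other* class label to its
    nearest-neighbor indices (ordered by ascending distance, ties broken
    by ascending sample index); each list holds ``min(k, class size)``
    entries. ``class_priors`` are the fractions p(C) of all samples in
    each class.
    """

    target_index: int
    same_class_neighbors: np.ndarray
    diff_class_neighbors: dict
    k: int
    class_priors: dict

    @property
    def same_class_empty(self) -> bool:
        return self.same_class_neighbors.size == 0


@dataclass(frozen=True)
class GeneWeightVector:
    """Per-gene Relief weights aligned to ``gene_ids``."""

    weights: np.ndarray
    gene_ids: tuple
    m: int
    k: int
    seed: int

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or w.size != len(self.gene_ids):
            raise ValueError("weights must be 1-D and aligned to gene_ids")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")


def euclidean_distance(x: int, y: int, genes, dataset: ExpressionDataset) -> float:
    """Euclidean distance between samples *x* and *y* over a gene subset."""
    genes = np.atleast_1d(np.asarray(genes, dtype=int))
    if genes.size == 0:
        raise ValueError("gene set must be non-empty")
    d = dataset.values[x, genes] - dataset.values[y, genes]
    return float(np.sqrt(np.dot(d, d)))


def _distances_to_all(values: np.ndarray, target: int) -> np.ndarray:
    diff = values - values[target]
    return np.sqrt(np.einsum("ij,ij->i", diff, diff))


def _ordered_neighbors(candidates: np.ndarray, dists: np.ndarray, k: int) -> np.ndarray:
    """Candidates sorted by (distance, sample index), truncated to k."""
    order = np.lexsort((candidates, dists[candidates]))
    return candidates[order[:k]]


def find_neighbors(dataset: ExpressionDataset, target: int, k: int,
                   genes=None) -> NeighborContext:
    """Hit and per-class miss neighborhoods of *target*.

    Distances are Euclidean over *genes* (all genes when omitted).
    Neighbor lists are ordered by ascending distance with ties broken by
    ascending sample index; the target itself is excluded everywhere.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = dataset.values if genes is None else dataset.values[:, np.asarray(genes, int)]
    dists = _distances_to_all(values, target)
    labels = dataset.label_array()
    target_class = labels[target]

    idx = np.arange(dataset.n_samples)
    same = idx[(labels == target_class) & (idx != target)]
    hits = _ordered_neighbors(same, dists, k)

    misses = {}
    for c in dataset.class_set:
        if c == target_class:
            continue
        members = idx[labels == c]
        misses[c] = _ordered_neighbors(members, dists, k)

    return NeighborContext(
        target_index=target,
        same_class_neighbors=hits,
        diff_class_neighbors=misses,
        k=k,
        class_priors=dataset.class_priors(),
    )


def _gene_ranges(dataset: ExpressionDataset) -> np.ndarray:
    return dataset.values.max(axis=0) - dataset.values.min(axis=0)


def same_class_distance(dataset: ExpressionDataset, ctx: NeighborContext,
                        gene: int) -> float:
    """Range-normalized distance of the target to its hit centroid on one gene.

    ``|v(x_i, gene) - mean over hits| / (max(gene) - min(gene))``, with the
    range taken over all samples. A constant gene contributes 0.
    """
    if ctx.same_class_empty:
        raise ValueError("target has no same-class neighbors; skip this term")
    v = dataset.values
    rng = v[:, gene].max() - v[:, gene].min()
    if rng == 0:
        return 0.0
    hbar = v[ctx.same_class_neighbors, gene].mean()
    return float(abs(v[ctx.target_index, gene] - hbar) / rng)


def diff_class_distance(dataset: ExpressionDataset, ctx: NeighborContext,
                        gene: int) -> float:
    """Prior-weighted, range-normalized distance to the miss centroids.

    Sum over other classes C of ``p(C)/(1 - p(class(x_i)))`` times the
    normalized distance of the target to C's neighbor centroid on the
    gene; the prior factors sum to 1 over the other classes.
    """
    if not ctx.diff_class_neighbors:
        raise ValueError("no other class present")
    v = dataset.values
    rng = v[:, gene].max() - v[:, gene].min()
    if rng == 0:
        return 0.0
    labels = dataset.label_array()
    p_self = ctx.class_priors[labels[ctx.target_index]]
    total = 0.0
    for c, members in ctx.diff_class_neighbors.items():
        factor = ctx.class_priors[c] / (1.0 - p_self)
        mbar = v[members, gene].mean()
        total += factor * abs(v[ctx.target_index, gene] - mbar) / rng
    return float(total)


def distance_coefficient(values) -> float:
    """Dispersion ratio of a vector: population std over absolute sum.

    Zero for a constant vector and, as a degenerate guard, when the sum
    is zero. Scale-invariant under positive scaling.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("distance coefficient of an empty vector")
    s = v.sum()
    if s == 0:
        return 0.0
    sd = np.sqrt(np.mean((v - v.mean()) ** 2))
    return float(sd / abs(s))


def draw_sample_indices(n_samples: int, m: int, seed: int) -> np.ndarray:
    """The seeded with-replacement sample draws both weight updaters use."""
    return np.random.default_rng(seed).integers(0, n_samples, size=m)


def _neighbor_sets(dists: np.ndarray, labels: np.ndarray, class_set,
                   target: int, k: int):
    """(hit indices, {class: miss indices}) under the shared tie rules."""
    idx = np.arange(labels.size)
    target_class = labels[target]
    same = idx[(labels == target_class) & (idx != target)]
    hits = _ordered_neighbors(same, dists, k)
    misses = {}
    for c in class_set:
        if c == target_class:
            continue
        misses[c] = _ordered_neighbors(idx[labels == c], dists, k)
    return hits, misses


def improved_relieff_weights(dataset: ExpressionDataset, m: int, k: int,
                             seed: int) -> GeneWeightVector:
    """Centroid/distance-coefficient ReliefF weights.

    Starting from all-zero weights, repeats ``m`` times: draw a sample,
    find its hit and per-class miss neighborhoods over all genes, then
    for every gene subtract ``CD_same * k_hits * hit-centroid-term /
    (m*k)`` and add ``CD_diff * sum_C prior_C * k_miss_C *
    miss-centroid-term_C / (m*k)``. ``CD_same``/``CD_diff`` are the
    distance coefficients of the Euclidean distances (over all genes)
    from the drawn sample to its hit neighbors and to the pooled miss
    neighbors.
    """
    if m < 1 or k < 1:
        raise ValueError("m and k must be >= 1")
    values = dataset.values
    n, p = values.shape
    ranges = _gene_ranges(dataset)
    inv_range = np.where(ranges > 0, 1.0 / np.where(ranges > 0, ranges, 1.0), 0.0)
    labels = dataset.label_array()
    priors = dataset.class_priors()
    class_set = dataset.class_set

    W = np.zeros(p)
    denom = m * k
    for x in draw_sample_indices(n, m, seed):
        dists = _distances_to_all(values, x)
        hits, misses = _neighbor_sets(dists, labels, class_set, x, k)

        if hits.size:
            cd_same = distance_coefficient(dists[hits])
            term = np.abs(values[x] - values[hits].mean(axis=0)) * inv_range
            W -= cd_same * hits.size * term / denom

        pooled = np.concatenate([dists[mi] for mi in misses.values()])
        cd_diff = distance_coefficient(pooled)
        p_self = priors[labels[x]]
        for c, mi in misses.items():
            factor = priors[c] / (1.0 - p_self)
            term = np.abs(values[x] - values[mi].mean(axis=0)) * inv_range
            W += cd_diff * factor * mi.size * term / denom

    return GeneWeightVector(W, dataset.gene_ids, m, k, seed)


def classic_relieff_weights(dataset: ExpressionDataset, m: int, k: int,
                            seed: int) -> GeneWeightVector:
    """Standard multiclass ReliefF weights (per-neighbor diff terms).

    Uses the same sample draws, neighbor ordering and tie rules as
    :func:`improved_relieff_weights` so that any weight difference is
    attributable to the update formula alone.
    """
    if m < 1 or k < 1:
        raise ValueError("m and k must be >= 1")
    values = dataset.values
    n, p = values.shape
    ranges = _gene_ranges(dataset)
    inv_range = np.where(ranges > 0, 1.0 / np.where(ranges > 0, ranges, 1.0), 0.0)
    labels = dataset.label_array()
    priors = dataset.class_priors()
    class_set = dataset.class_set

    W = np.zeros(p)
    denom = m * k
    for x in draw_sample_indices(n, m, seed):
        dists = _distances_to_all(values, x)
        hits, misses = _neighbor_sets(dists, labels, class_set, x, k)

        if hits.size:
            W -= (np.abs(values[x] - values[hits]) * inv_range).sum(axis=0) / denom

        p_self = priors[labels[x]]
        for c, mi in misses.items():
            factor = priors[c] / (1.0 - p_self)
            W += factor * (np.abs(values[x] - values[mi]) * inv_range).sum(axis=0) / denom

    return GeneWeightVector(W, dataset.gene_ids, m, k, seed)


def filter_top_genes(weights: GeneWeightVector, n_keep: int) -> np.ndarray:
    """Indices of the ``n_keep`` highest-weight genes, descending.

    Ties are broken by ascending gene index, so the ordering (used
    downstream as the candidate ranking) is fully deterministic.
    """
    w = weights.weights
    if not 1 <= n_keep <= w.size:
        raise ValueError(f"n_keep must be in [1, {w.size}], got {n_keep}")
    order = np.lexsort((np.arange(w.size), -w))
    return order[:n_keep]
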