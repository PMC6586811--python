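"""End-to-end hybrid filter-wrapper gene selection.

The full run chains: improved ReliefF weighting -> top-``filter_n``
ranking -> mean-weight pruning -> ant-colony subset search scored by
cross-validated classification accuracy -> best subset report.

The evaluation classifier defaults to 1-nearest-neighbor, consistent
with the neighbor-based rationale of the Relief filter; it is pluggable
(registry names or any scikit-learn estimator factory). Cross-validation
is stratified with seeded shuffling; when the smallest class has fewer
samples than the requested fold count, the fold count is reduced to that
class size with a warning.

Caveat: by default the accuracy reported for the selected subset is
cross-validated on the same data the search used, so it is an optimistic
(selection-biased) estimate. An external-holdout mode
(``RunConfig.holdout_fraction > 0``) splits off a stratified test set
before any selection and reports accuracy on it separately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .aco import ACOConfig, SelectionResult, prune_by_mean_weight, run_colony
from .dataio import ExpressionDataset
from .relieff import filter_top_genes, improved_relieff_weights

__all__ = [
    "RunConfig",
    "SelectionResult",
    "crossval_accuracy",
    "run_rfaco_gs",
    "make_classifier",
    "CLASSIFIERS",
]

logger = logging.getLogger("rfacogs")

CLASSIFIERS = {
    "1nn": lambda: KNeighborsClassifier(n_neighbors=1),
    "3nn": lambda: KNeighborsClassifier(n_neighbors=3),
    "svm-linear": lambda: SVC(kernel="linear"),
    "tree": lambda: DecisionTreeClassifier(random_state=0),
}


def make_classifier(classifier):
    """Resolve a registry name or estimator factory to a fresh estimator."""
    if callable(classifier):
        return classifier()
    try:
        return CLASSIFIERS[classifier]()
    except KeyError:
        raise ValueError(
            f"unknown classifier {classifier!r}; known: {sorted(CLASSIFIERS)}"
        ) from None


@dataclass
class RunConfig:
    """Parameters of a full selection run.

    ``relieff_m`` defaults to the sample count when left ``None``;
    ``filter_n`` is the number of top-weighted genes handed from the
    filter to the wrapper.
    """

    relieff_m: int | None = None
    relieff_k: int = 10
    relieff_seed: int = 0
    filter_n: int = 100
    aco: ACOConfig = field(default_factory=ACOConfig)
    classifier: str = "1nn"
    cv_folds: int = 10
    cv_seed: int = 0
    holdout_fraction: float = 0.0

    def __post_init__(self):
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0.0 <= self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must lie in [0, 1)")


def crossval_accuracy(dataset: ExpressionDataset, genes, classifier="1nn",
                      folds: int = 10, seed: int = 0) -> float:
    """Mean held-out accuracy over a seeded stratified k-fold partition.

    The classifier is trained per fold on the given gene subset only.
    The fold count is reduced to the smallest class size when necessary
    (with a warning); a smallest class of one sample cannot be folded
    and raises.
    """
    genes = np.atleast_1d(np.asarray(genes, dtype=int))
    if genes.size == 0:
        raise ValueError("gene subset must be non-empty")
    X = dataset.values[:, genes]
    y = np.asarray(dataset.labels)

    _, counts = np.unique(y, return_counts=True)
    smallest = int(counts.min())
    if smallest < 2:
        raise ValueError(
            "stratified cross-validation needs every class in at least 2 samples"
        )
    eff_folds = min(folds, smallest)
    if eff_folds < folds:
        warnings.warn(
            f"reducing folds from {folds} to {eff_folds}: smallest class has "
            f"{smallest} samples",
            stacklevel=2,
        )

    skf = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(X, y):
        clf = make_classifier(classifier)
        clf.fit(X[train], y[train])
        accs.append(float(np.mean(clf.predict(X[test]) == y[test])))
    return float(np.mean(accs))


def run_rfaco_gs(dataset: ExpressionDataset, config: RunConfig) -> SelectionResult:
    """Full hybrid run: filter, prune, colony search, best-subset report.

    Stage sizes (genes in -> after filter -> after pruning -> selected)
    are logged and recorded in the result's config. If pruning leaves
    fewer candidates than the ant subset size, the candidate set falls
    back to the top ``subset_size`` genes of the filtered ranking.
    """
    work = dataset
    holdout = None
    if config.holdout_fraction > 0:
        idx_train, idx_test = train_test_split(
            np.arange(dataset.n_samples),
            test_size=config.holdout_fraction,
            stratify=list(dataset.labels),
            random_state=config.cv_seed,
        )
        work = _subset_samples(dataset, idx_train)
        holdout = (idx_train, idx_test)

    m = config.relieff_m if config.relieff_m is not None else work.n_samples
    filter_n = min(config.filter_n, work.n_genes)

    weights = improved_relieff_weights(work, m=m, k=config.relieff_k,
                                       seed=config.relieff_seed)
    filtered = filter_top_genes(weights, filter_n)
    pruned = prune_by_mean_weight(weights, filtered)
    if pruned.size < config.aco.subset_size:
        pruned = filtered[: config.aco.subset_size]

    logger.info(
        "stage sizes: %d genes in -> %d after filter -> %d after pruning",
        work.n_genes, filtered.size, pruned.size,
    )

    def evaluator(genes):
        return crossval_accuracy(work, genes, classifier=config.classifier,
                                 folds=config.cv_folds, seed=config.cv_seed)

    result = run_colony(work, pruned, weights, config.aco, evaluator)

    full_config = {
        "relieff": {"m": m, "k": config.relieff_k, "seed": config.relieff_seed},
        "filter_n": filter_n,
        "aco": asdict(config.aco),
        "classifier": config.classifier if isinstance(config.classifier, str)
        else getattr(config.classifier, "__name__", "custom"),
        "cv_folds": config.cv_folds,
        "cv_seed": config.cv_seed,
        "holdout_fraction": config.holdout_fraction,
        "stage_sizes": {
            "input": work.n_genes,
            "after_filter": int(filtered.size),
            "after_pruning": int(pruned.size),
            "selected": int(result.selected_indices.size),
        },
    }
    if holdout is not None:
        idx_train, idx_test = holdout
        clf = make_classifier(config.classifier)
        clf.fit(dataset.values[np.ix_(idx_train, result.selected_indices)],
                [dataset.labels[i] for i in idx_train])
        pred = clf.predict(dataset.values[np.ix_(idx_test, result.selected_indices)])
        truth = np.asarray([dataset.labels[i] for i in idx_test])
        full_config["holdout_accuracy"] = float(np.mean(pred == truth))
    result.config = full_config

    logger.info("selected %d genes, cv accuracy %.4f",
                result.selected_indices.size, result.cv_accuracy)
    return result


def _subset_samples(dataset: ExpressionDataset, indices) -> ExpressionDataset:
    idx = np.asarray(indices, dtype=int)
    return ExpressionDataset(
        dataset.values[idx],
        dataset.gene_ids,
        tuple(dataset.sample_ids[i] for i in idx),
        tuple(dataset.labels[i] for i in idx),
    )
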