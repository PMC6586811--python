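"""Ant-colony subset search over a filtered candidate gene set.

Genes are nodes of a complete graph; an ant builds a fixed-size gene
subset by walking from gene to gene, biased by pheromone laid on edges
by earlier ants and by a static per-edge *visibility* (reciprocal
Euclidean distance between the two genes' expression vectors across
samples). Two rule sets are available:

classic
    Transition score ``tau_ij^alpha * eta_ij^beta``; pheromone update
    ``tau <- (1 - rho) tau + sum of Q / L_k deposits`` over the ants that
    traversed the edge, with ``L_k`` the ant's path length.

improved
    Transition score ``tau_ij^omega_j * eta_ij^|r_ij|`` where ``omega_j``
    derives from the absolute Relief weight of the destination gene and
    ``r_ij`` is the Pearson correlation of the two genes, so the walk
    prefers weighty, strongly co-varying partners; the pheromone update
    additionally adds the destination gene's absolute weight on every
    edge traversed in the cycle, reinforcing important genes so their
    pheromone is not overwhelmed by evaporation.

A *pruning rule* ahead of the search keeps only candidates whose weight
exceeds the candidate-set mean.

The quantity that ranks subsets (and defines the returned best) is a
caller-supplied evaluator — in the full pipeline, cross-validated
classification accuracy. Pheromone deposits default to the path-length
fitness ``Q / L_k``; an accuracy-proportional deposit ``Q * accuracy``
is available via ``ACOConfig.deposit``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .dataio import ExpressionDataset
from .relieff import GeneWeightVector

__all__ = [
    "ACOConfig",
    "PheromoneState",
    "AntPath",
    "SelectionResult",
    "ColonyEvaluationError",
    "prune_by_mean_weight",
    "pearson_correlation",
    "visibility",
    "initialize_state",
    "transition_probabilities",
    "construct_ant_path",
    "path_length",
    "deposit_amount",
    "update_pheromone",
    "run_colony",
]

#: distance floor for visibility / deposit on degenerate (zero-length) edges
EPS = 1e-12


@dataclass
class ACOConfig:
    """Colony parameters.

    Defaults follow the standard setup for this search: 100 ants, 80
    iterations, pheromone deposit constant Q = 100, evaporation rate
    rho = 0.1 and unit initial pheromone.
    """

    n_ants: int = 100
    n_iterations: int = 80
    rho: float = 0.1
    Q: float = 100.0
    tau0: float = 1.0
    subset_size: int = 10
    alpha: float = 1.0
    beta: float = 1.0
    rule_set: str = "improved"
    seed: int = 0
    omega_min: float = 0.1
    raw_omega: bool = False
    deposit: str = "path_length"  # or "accuracy"

    def __post_init__(self):
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (0, 1)")
        if self.tau0 <= 0:
            raise ValueError("tau0 must be positive")
        if self.n_ants < 1 or self.n_iterations < 0 or self.subset_size < 1:
            raise ValueError("n_ants >= 1, n_iterations >= 0, subset_size >= 1")
        if self.rule_set not in ("classic", "improved"):
            raise ValueError("rule_set must be 'classic' or 'improved'")
        if self.deposit not in ("path_length", "accuracy"):
            raise ValueError("deposit must be 'path_length' or 'accuracy'")


@dataclass
class PheromoneState:
    """Pheromone, visibility and correlation over a candidate gene set.

    All matrices are square over the candidates (diagonal unused);
    ``tau`` is kept symmetric. ``omega`` holds the transition-rule
    exponents (rescaled absolute weights by default) and ``abs_weights``
    the raw absolute Relief weights added in the improved pheromone
    update. Indices passed to the transition/path functions are
    positions within ``candidates``.
    """

    candidates: np.ndarray
    tau: np.ndarray
    eta: np.ndarray
    corr: np.ndarray
    omega: np.ndarray
    abs_weights: np.ndarray
    iteration: int = 0

    def snapshot(self) -> dict:
        """Structured text-serializable dump for debugging."""
        return {
            "iteration": self.iteration,
            "candidates": self.candidates.tolist(),
            "tau_mean": float(self.tau[~np.eye(len(self.candidates), dtype=bool)].mean()),
            "tau_max": float(self.tau.max()),
            "omega": self.omega.tolist(),
        }


@dataclass
class AntPath:
    """One ant's walk: distinct genes, the subset fitness, and Eq-style path length.

    ``genes`` are dataset gene indices; ``local`` the same genes as
    positions within the candidate set.
    """

    genes: np.ndarray
    local: tuple
    fitness: float = float("nan")
    length: float = float("nan")


@dataclass
class SelectionResult:
    """Final selected subset with provenance.

    ``selected_genes`` are gene identifiers (ascending dataset order);
    ``cv_accuracy`` the evaluator score of that subset; ``history`` one
    record per colony iteration; ``config`` the full parameter dict.
    """

    selected_genes: tuple
    selected_indices: np.ndarray
    cv_accuracy: float
    weights_snapshot: GeneWeightVector
    history: list
    config: dict
    seed: int


class ColonyEvaluationError(RuntimeError):
    """The subset evaluator failed; carries the offending subset."""

    def __init__(self, subset, cause):
        self.subset = tuple(int(g) for g in subset)
        super().__init__(f"evaluator failed on gene subset {self.subset}: {cause}")


def prune_by_mean_weight(weights: GeneWeightVector, candidates) -> np.ndarray:
    """Keep candidates whose weight strictly exceeds the candidate-set mean.

    Input order is preserved. If the strict rule would empty the set
    (all candidate weights equal) the candidates are returned unchanged.
    """
    cand = np.atleast_1d(np.asarray(candidates, dtype=int))
    if cand.size == 0:
        raise ValueError("candidate set must be non-empty")
    w = weights.weights[cand]
    keep = cand[w > w.mean()]
    return cand.copy() if keep.size == 0 else keep


def pearson_correlation(gene_i: int, gene_j: int,
                        dataset: ExpressionDataset) -> float:
    """Sample Pearson correlation of two genes across all samples.

    Defined as 0 when either gene is constant (the correlation is then
    undefined and the pair carries no co-variation signal).
    """
    x = dataset.values[:, gene_i]
    y = dataset.values[:, gene_j]
    if x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(np.clip(r, -1.0, 1.0))


def visibility(gene_i: int, gene_j: int, dataset: ExpressionDataset,
               eps: float = EPS) -> float:
    """Reciprocal Euclidean distance between two genes' expression vectors.

    Identical genes (distance 0) get ``1/eps`` rather than infinity.
    """
    d = dataset.values[:, gene_i] - dataset.values[:, gene_j]
    dist = float(np.sqrt(np.dot(d, d)))
    return 1.0 / (dist if dist > 0 else eps)


def _correlation_matrix(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values.T)
    corr = np.atleast_2d(corr)
    corr[~np.isfinite(corr)] = 0.0  # constant genes: undefined -> 0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def initialize_state(dataset: ExpressionDataset, candidates,
                     weights: GeneWeightVector, config: ACOConfig) -> PheromoneState:
    """Build the pheromone/visibility/correlation state for a candidate set."""
    cand = np.atleast_1d(np.asarray(candidates, dtype=int))
    if cand.size < 2:
        raise ValueError("need at least 2 candidate genes")
    sub = dataset.values[:, cand]

    dmat = squareform(pdist(sub.T, metric="euclidean"))
    eta = 1.0 / np.where(dmat > 0, dmat, EPS)
    np.fill_diagonal(eta, 0.0)  # diagonal unused

    corr = _correlation_matrix(sub)

    absw = np.abs(weights.weights[cand])
    if config.raw_omega:
        omega = absw.copy()
    else:
        lo, hi = absw.min(), absw.max()
        if hi == lo:
            omega = np.ones_like(absw)
        else:
            omega = config.omega_min + (1.0 - config.omega_min) * (absw - lo) / (hi - lo)

    tau = np.full((cand.size, cand.size), float(config.tau0))
    np.fill_diagonal(tau, 0.0)
    return PheromoneState(candidates=cand, tau=tau, eta=eta, corr=corr,
                          omega=omega, abs_weights=absw)


def transition_probabilities(state: PheromoneState, current: int, allowed,
                             config: ACOConfig) -> np.ndarray:
    """Probability of moving from *current* to each gene in *allowed*.

    Indices are positions within ``state.candidates``. Improved rule:
    ``tau_ij^omega_j * eta_ij^|r_ij|``; classic rule: ``tau^alpha *
    eta^beta``. Scores are computed in log space with max-subtraction;
    if every score degenerates to zero the distribution is uniform.
    """
    allowed = np.atleast_1d(np.asarray(allowed, dtype=int))
    if allowed.size == 0:
        raise ValueError("allowed set must be non-empty")
    if current in allowed:
        raise ValueError("current gene cannot be in the allowed set")

    tau = state.tau[current, allowed]
    eta = state.eta[current, allowed]
    if config.rule_set == "improved":
        e_tau = state.omega[allowed]
        e_eta = np.abs(state.corr[current, allowed])
    else:
        e_tau = np.full(allowed.size, float(config.alpha))
        e_eta = np.full(allowed.size, float(config.beta))

    with np.errstate(divide="ignore"):
        log_tau = np.log(tau)
        log_eta = np.log(eta)
    # x^0 == 1 even at x == 0: a zero exponent contributes nothing
    t1 = np.where(e_tau == 0, 0.0, e_tau * log_tau)
    t2 = np.where(e_eta == 0, 0.0, e_eta * log_eta)
    logs = t1 + t2

    mx = np.max(logs)
    if not np.isfinite(mx):
        return np.full(allowed.size, 1.0 / allowed.size)
    scores = np.exp(logs - mx)
    total = scores.sum()
    if total == 0 or not np.isfinite(total):
        return np.full(allowed.size, 1.0 / allowed.size)
    return scores / total


def construct_ant_path(state: PheromoneState, config: ACOConfig,
                       rng: np.random.Generator) -> AntPath:
    """Build one ant's subset: uniform start, then transition-rule steps."""
    c = state.candidates.size
    if config.subset_size > c:
        raise ValueError("subset_size exceeds candidate count")
    visited = [int(rng.integers(c))]
    unvisited = np.ones(c, dtype=bool)
    unvisited[visited[0]] = False
    while len(visited) < config.subset_size:
        allowed = np.flatnonzero(unvisited)
        probs = transition_probabilities(state, visited[-1], allowed, config)
        nxt = int(rng.choice(allowed, p=probs))
        visited.append(nxt)
        unvisited[nxt] = False
    return AntPath(genes=state.candidates[np.asarray(visited)], local=tuple(visited))


def path_length(path: AntPath, dataset: ExpressionDataset) -> float:
    """Sum of Euclidean gene-to-gene distances along the walk.

    A single-gene path has length 0 by convention.
    """
    genes = np.asarray(path.genes, dtype=int)
    if genes.size < 2:
        return 0.0
    cols = dataset.values[:, genes]
    seg = cols[:, 1:] - cols[:, :-1]
    return float(np.sqrt((seg ** 2).sum(axis=0)).sum())


def deposit_amount(Q: float, L_k: float, eps: float = EPS) -> float:
    """Pheromone laid by one ant: ``Q / L_k`` (``Q / eps`` on a zero-length path)."""
    return Q / (L_k if L_k > 0 else eps)


def update_pheromone(state: PheromoneState, paths, config: ACOConfig) -> PheromoneState:
    """One evaporation-plus-deposit cycle over all ant paths, in place.

    Every edge evaporates by ``(1 - rho)``; each ant adds its deposit to
    both directions of every edge it traversed; under the improved rule
    each *directed* traversed edge (i -> j) additionally receives the
    destination gene's absolute Relief weight once per cycle. Symmetry is
    restored by averaging the two directional updates.
    """
    if not paths:
        raise ValueError("paths must be non-empty")
    c = state.candidates.size
    M = (1.0 - config.rho) * state.tau
    traversed = np.zeros((c, c), dtype=bool)
    for p in paths:
        if config.deposit == "accuracy":
            d = config.Q * p.fitness
        else:
            d = deposit_amount(config.Q, p.length)
        for a, b in zip(p.local[:-1], p.local[1:]):
            M[a, b] += d
            M[b, a] += d
            traversed[a, b] = True
    if config.rule_set == "improved":
        M = M + traversed * state.abs_weights[None, :]
    tau = (M + M.T) / 2.0
    np.fill_diagonal(tau, 0.0)
    state.tau = tau
    state.iteration += 1
    return state


def run_colony(dataset: ExpressionDataset, candidates,
               weights: GeneWeightVector, config: ACOConfig,
               evaluator) -> SelectionResult:
    """Run the colony and return the best-evaluated gene subset.

    *candidates* must already be filtered/pruned and ordered by
    descending weight; *evaluator* maps a gene-index array to a score in
    [0, 1] (cross-validated accuracy in the full pipeline). The best
    subset ever evaluated is tracked across iterations (ties keep the
    earlier subset); per-iteration history records best/mean fitness and
    a pheromone summary, plus the candidate re-ranking by pheromone mass
    carried into the next iteration.

    With ``n_iterations == 0`` the colony is skipped and the evaluator is
    scored once on the top ``subset_size`` candidates by weight.
    """
    cand = np.atleast_1d(np.asarray(candidates, dtype=int))
    if cand.size == 0:
        raise ValueError("candidate set must be non-empty")
    if config.subset_size > cand.size:
        raise ValueError("subset_size exceeds candidate count")

    cache = {}

    def evaluate(genes: np.ndarray) -> float:
        key = tuple(sorted(int(g) for g in genes))
        if key not in cache:
            try:
                cache[key] = float(evaluator(np.asarray(key, dtype=int)))
            except Exception as exc:  # noqa: BLE001 - contract: report subset
                raise ColonyEvaluationError(key, exc) from exc
        return cache[key]

    history = []
    gene_ids = dataset.gene_ids

    if config.n_iterations == 0:
        top = cand[: config.subset_size]
        acc = evaluate(top)
        best_genes, best_acc = np.sort(top), acc
    else:
        state = initialize_state(dataset, cand, weights, config)
        rng = np.random.default_rng(config.seed)
        best_genes, best_acc = None, -np.inf
        for t in range(config.n_iterations):
            paths = [construct_ant_path(state, config, rng)
                     for _ in range(config.n_ants)]
            for p in paths:
                p.length = path_length(p, dataset)
                p.fitness = evaluate(p.genes)
                if p.fitness > best_acc:
                    best_acc = p.fitness
                    best_genes = np.sort(p.genes)
            update_pheromone(state, paths, config)
            mass = state.tau.sum(axis=0)
            ranking = cand[np.lexsort((np.arange(cand.size), -mass))]
            fits = np.array([p.fitness for p in paths])
            history.append({
                "iteration": t,
                "best_fitness": float(fits.max()),
                "mean_fitness": float(fits.mean()),
                "best_so_far": float(best_acc),
                "tau_mean": float(state.tau[~np.eye(cand.size, dtype=bool)].mean()),
                "tau_max": float(state.tau.max()),
                "gene_ranking": [int(g) for g in ranking],
            })

    return SelectionResult(
        selected_genes=tuple(gene_ids[int(g)] for g in best_genes),
        selected_indices=np.asarray(best_genes, dtype=int),
        cv_accuracy=float(best_acc),
        weights_snapshot=weights,
        history=history,
        config=asdict(config),
        seed=config.seed,
    )
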