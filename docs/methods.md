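# Methods

## Problem setting

Tumor classification from expression microarrays is a small-n / large-p
problem: typically 60–200 labeled samples over 2,000–13,000 genes, of
which only a handful carry class signal. `rfacogs` selects a small gene
subset in two stages — a filter that is cheap over all genes, and a
wrapper that is accurate over few — so that a downstream classifier sees
only informative, weakly redundant features.

## Filter: Relief-family gene weighting

Relief-type algorithms score a gene by contrasting a sample's nearest
*hits* (neighbors in its own class) with its nearest *misses* (neighbors
in each other class). The classic multiclass update, repeated for `m`
randomly drawn samples with `k` neighbors per class, is

    W[g] <- W[g] - sum_j diff(g, x, H_j) / (m k)
                 + sum_{C != class(x)} p(C)/(1 - p(class(x)))
                   * sum_j diff(g, x, M_j(C)) / (m k)

with `diff` the per-gene absolute difference normalized by the gene's
range over all samples. A gene whose hits look like the sample but whose
misses do not accumulates positive weight.

The improved update replaces the per-neighbor sum by a **centroid
distance** — the sample's distance to the *mean* of its k hits (misses)
on the gene, multiplied by the realized neighbor count so the magnitude
matches the classic per-neighbor sum — and scales each term by a
**distance coefficient** CD: the population standard deviation of the
Euclidean distances from the sample to those neighbors divided by the
absolute sum of those distances. Draws whose neighborhoods are erratic
(high relative dispersion of neighbor distances) are damped less on the
between-class side and more on the within-class side, stabilizing the
weights across the random draws.

Numerical and procedural choices:

* **CD formula.** A literal "sum of deviations" numerator is identically
  zero for every input; we use squared deviations (population standard
  deviation over |sum|), the only reading under which CD grows with the
  variation of its input. CD of a constant vector, or of a vector with
  zero sum, is defined as 0.
* **CD inputs.** CD_same is computed from the vector of Euclidean
  distances (over all genes) from the drawn sample to its k hits;
  CD_diff from the pooled distances to all miss neighbors.
* **Centroid x k_used.** The per-neighbor sum over j = 1..k is realized
  as the centroid term times the realized neighbor count (classes
  smaller than k contribute what they have); for the between-class term
  this multiplier is applied per class inside the prior-weighted sum.
* **Range normalization** is per gene over all samples; a constant gene
  contributes exactly 0 rather than a division error, so its final
  weight is exactly 0.
* **Sampling.** The m repeats draw samples uniformly *with replacement*,
  as `default_rng(seed).integers(0, n_samples, m)`. This draw sequence
  is part of the determinism contract: identical `(dataset, m, k, seed)`
  give bitwise-identical weights. Defaults: `k = 10`, `m = n_samples`.
* **Ties** in neighbor search are broken by ascending sample index.

Both update rules share the sampling, neighbor-search and tie-break
machinery, so comparing them isolates the formula change.

## Pruning

After ranking, the top `filter_n` genes (default 100) are handed to the
wrapper, and of those only the genes whose weight strictly exceeds the
candidate-set mean are retained. If all candidate weights are equal the
strict rule would discard everything, so the set is returned unchanged.
If pruning leaves fewer genes than the ant subset size, the candidate
set falls back to the top `subset_size` genes of the filtered ranking.

## Wrapper: ant-colony subset search

Candidate genes are nodes of a complete graph. Each ant starts at a
uniformly drawn gene and repeatedly steps to an unvisited gene until it
has collected `subset_size` genes. The step distribution from gene i is
proportional to

    tau_ij ^ omega_j  *  eta_ij ^ |r_ij|        (improved rule)
    tau_ij ^ alpha    *  eta_ij ^ beta          (classic rule)

where `tau` is pheromone, `eta_ij = 1 / d_ij` the reciprocal Euclidean
distance between the two genes' expression vectors, `r_ij` their Pearson
correlation, and `omega_j` derives from the absolute Relief weight of
the destination gene. After each cycle every edge evaporates by
`(1 - rho)` and each ant deposits `Q / L_k` on both directions of every
edge it traversed, with `L_k` its path length (the summed gene-to-gene
distances); under the improved rule each *directed* traversed edge
(i -> j) additionally receives the destination's absolute Relief weight
once per cycle, so important genes keep pheromone against evaporation.
Symmetry of `tau` is restored by averaging the two directional updates.

Defaults: 100 ants, 80 iterations, `rho = 0.1`, `Q = 100`, `tau0 = 1`.

Design choices in the open corners:

* **Initial pheromone.** Zero initialization makes every transition
  score identically zero, so `tau(0) = tau0 > 0` (default 1.0) is used.
* **Correlation exponent.** A raw correlation exponent can be negative,
  which would invert the intended preference; the absolute value |r| is
  used. Note that on raw expression scales gene-to-gene distances are
  large, so `eta < 1` and the |r| exponent actually *down-weights*
  strongly correlated partners — a real property of the rule as defined
  (see Limitations).
* **omega.** Absolute improved-ReliefF weights rescaled to
  `[omega_min, 1]` (default `omega_min = 0.1`) so pheromone exponents
  stay in a sane range; raw weights by flag. The weight added in the
  pheromone update is the *unrescaled* absolute weight.
* **Weight term scope.** The destination-weight bonus applies only to
  edges traversed in the current cycle; applying it to all edges would
  grow pheromone without bound on never-visited edges.
* **Fitness duality.** Pheromone deposits default to the path-length
  fitness `Q / L_k`; the quantity that *ranks* subsets and defines the
  returned best is the evaluator — 10-fold cross-validated accuracy in
  the full pipeline. An accuracy-proportional deposit (`Q * accuracy`)
  is available via `ACOConfig.deposit = "accuracy"`.
* **Carrying genes forward.** After each iteration the candidates are
  re-ranked by pheromone mass (column sums of tau) and the ranking is
  recorded in the history; the candidate set itself is held fixed across
  iterations so the search never starves. The best-evaluated subset is
  tracked across all iterations (ties keep the earlier subset) and is
  what the run returns.
* **Numerics.** Transition scores are computed in log space with
  max-subtraction; a zero exponent contributes nothing even at
  `tau = 0`; an all-degenerate score vector falls back to uniform.
  Zero gene-to-gene distances use `epsilon = 1e-12` in visibility and
  deposits. Evaluator calls are cached per gene set (the evaluator is
  deterministic given its seed), which does not affect the random
  stream.

## Evaluation

`crossval_accuracy` is mean held-out accuracy over seeded stratified
k-fold CV (default 10 folds), training the classifier per fold on the
candidate gene subset only. The default classifier is 1-nearest-neighbor
— consistent with the neighbor-based rationale of the filter — with
3-NN, linear SVM and a decision tree available, and any estimator
factory accepted. When the smallest class has fewer samples than the
requested folds, the fold count is reduced to that class size with a
warning.

By default the reported accuracy is cross-validated on the same data the
search optimized, so it is selection-biased upward; it measures search
quality, not generalization. `RunConfig.holdout_fraction > 0` splits off
a stratified test set before any selection and additionally reports
accuracy there.

## Synthetic data

The generator emulates the small-n / large-p regime with a Gaussian
class-conditional model chosen for analytic control of effect sizes:
an informative gene's mean in class c is `c * effect_size * noise_sd`
with within-class standard deviation `noise_sd` (so `effect_size` is a
standardized mean difference between adjacent classes); redundant genes
are informative genes plus independent `N(0, redundancy_noise_sd)`
noise (expected parent correlation `sigma_p / sqrt(sigma_p^2 + s^2)`);
the rest are class-independent noise. Samples are apportioned to
classes by largest remainder, and gene columns are shuffled into random
positions so positional assumptions cannot pass recovery tests.

The standard study condition used throughout the tests and the
acceptance script is 100 samples x 500 genes with 10 informative genes
at effect size 1.5, 10 redundant copies at `redundancy_noise_sd = 1`,
and unit noise. What passing on this fixture shows: the filter ranks
planted signal above noise, and the wrapper finds a subset at least as
accurate as the full matrix and random subsets of equal size. What it
does not show: behavior under heavy-tailed intensities, batch effects,
missingness or correlated noise structure of real microarray platforms —
all deliberately out of scope for fixtures.

## Problem sizes in tests and the acceptance script

Oracle-equivalence checks run on fixtures up to 30 samples x 15 genes
(25 random instances) and on 1000 random instances per colony
operation. Recovery checks use the standard fixture above with the
colony at 30 ants x 20 iterations over 50 filtered candidates
(subset size 10), 5–10 generator seeds; the acceptance script reports
the filter recovery over 5 seeds and the pipeline comparison over 3
seeds. These sizes were chosen so a complete run is comfortable on a
single CPU while keeping sampling error well inside the asserted
margins.

## Known limitations

* With very small ant subsets (size 2) a subset is a single edge, and
  evaporation concentrates pheromone on short, weakly correlated edges
  within a few iterations; a specific pair is then only found if early
  iterations cover it. The pair-recovery test therefore front-loads its
  colony budget (many ants, few iterations). For realistic subset sizes
  (~10) membership does not require adjacency and this effect is
  immaterial.
* The path-length deposit rewards proximity of gene expression vectors,
  not accuracy; the accuracy signal enters through best-subset tracking
  and the weight terms. The accuracy-deposit mode aligns the positive
  feedback with the selection objective at the cost of extra evaluator
  calls on poor subsets.
* Weights from the improved update are not comparable in magnitude to
  classic ReliefF weights (the CD factors are data-dependent); only
  rankings should be compared across variants.
* The loader rejects missing values rather than imputing; matrices are
  taken as given (no log-transform or scaling is applied — the Relief
  distance operators normalize per gene by range internally).
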