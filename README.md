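# rfacogs

Hybrid filter–wrapper gene selection for tumor classification from
labeled gene-expression matrices.

Expression studies in the microarray regime have far more genes than
samples (thousands of genes, tens to a couple hundred samples), and most
genes are noise or redundant. `rfacogs` picks a small, highly
class-informative gene subset in two stages:

1. **Filter — improved ReliefF.** Relief-type weighting scores a gene by
   how well it separates a sample from its nearest *misses* (neighbors
   in other classes) relative to its nearest *hits* (neighbors in its
   own class). The improved update uses the distance of each drawn
   sample to its hit/miss neighbor *centroids* (range-normalized per
   gene) and scales both terms by a *distance coefficient* — the
   relative dispersion sd(d)/|Σd| of the sample's neighbor distances —
   which damps erratic draws and stabilizes weights across the `m`
   random repeats:

   `W[g] ← W[g] − CD_same · k · |v_g − H̄_g| / ((max_g−min_g) m k)
           + CD_diff · Σ_C p(C)/(1−p(class(x))) · k · |v_g − M̄_{C,g}| / ((max_g−min_g) m k)`

   The classic multiclass ReliefF update is implemented alongside, on
   identical sampling and tie rules, as a baseline.

2. **Wrapper — improved ant-colony optimization.** The top-ranked genes
   (pruned to those above the mean candidate weight) form a complete
   graph searched by ants. The transition rule
   `p_ij ∝ τ_ij^{ω_j} · η_ij^{|r_ij|}` biases the walk by pheromone τ,
   visibility η (reciprocal gene–gene distance) exponentiated by the
   Pearson correlation of the two genes, and the destination's Relief
   weight ω; the pheromone update `τ ← (1−ρ)τ + Σ Q/L_k + W[{j}]` adds
   the destination gene's absolute weight on traversed edges so
   important genes resist evaporation. Every ant's gene set is scored by
   seeded stratified 10-fold cross-validated accuracy (1-NN by default),
   and the best-scoring subset ever evaluated is returned.

A seeded synthetic-data generator with planted informative/redundant
genes makes every stage testable without external downloads.

## Worked example

```python
import numpy as np
from rfacogs import (SyntheticSpec, generate, RunConfig, ACOConfig,
                     run_rfaco_gs, crossval_accuracy)

# 100 samples x 500 genes; 10 informative genes at effect size 1.5,
# 10 redundant copies, the rest gaussian noise
dataset, truth = generate(SyntheticSpec(seed=3))

config = RunConfig(
    relieff_m=100, relieff_k=10, relieff_seed=3, filter_n=50,
    aco=ACOConfig(n_ants=30, n_iterations=20, subset_size=10, seed=3),
    cv_folds=10, cv_seed=3,
)
result = run_rfaco_gs(dataset, config)

print("selected:", result.selected_genes)
print("cv accuracy:", round(result.cv_accuracy, 3))
print("full-matrix accuracy:",
      round(crossval_accuracy(dataset, np.arange(dataset.n_genes), seed=3), 3))
print("stage sizes:", result.config["stage_sizes"])
```

Output:

```
selected: ('g0064', 'g0092', 'g0155', 'g0229', 'g0265', 'g0274', 'g0277', 'g0322', 'g0408', 'g0429')
cv accuracy: 0.97
full-matrix accuracy: 0.75
stage sizes: {'input': 500, 'after_filter': 50, 'after_pruning': 16, 'selected': 10}
```

The 10 selected genes (9 of them planted signal) classify at 97%
cross-validated accuracy where all 500 genes together reach 75% — the
noise genes actively hurt the 1-NN distance — and a random 10-gene
subset averages ~54%. Note the reported accuracy is cross-validated on
the data the search used, so it is an optimistic estimate of
generalization; see `RunConfig.holdout_fraction` and `docs/methods.md`.

## Command line

```bash
rfacogs synth --samples 100 --genes 500 --informative 10 --redundant 10 \
    --effect-size 1.5 --seed 1 --out expr.csv          # + expr.csv.truth.tsv
rfacogs weights --input expr.csv --k 10 --seed 1 --out weights.tsv
rfacogs run --input expr.csv --filter-n 50 --ants 30 --iterations 20 \
    --subset-size 10 --folds 10 --seed 1 --out results/
```

`rfacogs run` writes `weights.tsv` (gene_id, weight, rank, selected) and
`summary.json` (selected genes, CV accuracy, full config, per-iteration
history) under `--out`. All flags mirror a YAML config file (`--config`);
explicit flags win.

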