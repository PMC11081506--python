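# reset-gst

Single-sample gene set scoring for bulk and single-cell transcriptomics,
based on the error of a randomized reduced-rank reconstruction.

Given an expression matrix **X** (n samples/cells × p genes) and a
collection of m gene sets encoded as a binary annotation matrix **A**, the
method asks, for each set: *how well do this set's genes reconstruct the
dominant structure of the whole matrix?* It returns

- **S** (n × m): a score per sample and set, usable downstream wherever a
  gene-level matrix would be (differential testing, clustering,
  visualization), and
- **v** (length m): one overall score per set.

Unlike mean/rank-based single-sample methods, reconstruction-error scores
respond to *differential correlation* as well as differential abundance,
and scores for different sets are on a comparable scale, which makes
competitive questions ("which of these sets is active?") answerable
directly.

## Method

1. Column-center (optionally scale) **X** to get **X**_c, and project onto
   its top *b* principal components: **P** = **X**_c **V**[:, 1..b], with
   the SVD computed by a randomized sketch (Gaussian test matrix,
   oversampling *d*, *q* power iterations).
2. For each gene set i with l_i genes, build a rank-*k* orthonormal basis
   **Q**_s for the column space of the set's sub-matrix — by a randomized
   rangefinder when l_i > `random_threshold`, otherwise by column-pivoted
   QR — and form the reconstruction error **E** = **P** − **Q**_s**Q**_sᵀ**P**.
3. Score by log norm ratios:
   v_i = log2(‖**P**‖_F / ‖**E**‖_F) and
   S[j, i] = log2(‖**P**[j,]‖ / ‖**E**[j,]‖)
   (Euclidean row norms by default, L1 optional). An optional
   per-variable adjustment divides set i's scores by l_i / l̄, where l̄ is
   the collection's mean set size.

Sparse matrices are supported end-to-end: with delayed centering the full
matrix is never densified — the SVD runs on the uncentered sparse matrix,
and centering is applied to the PC projection and to each small per-set
sub-matrix only.

The package also ships the negative-binomial simulation designs used to
validate the method (a planted block of correlated, mean-inflated counts
in four configurations) and an AUC-based evaluation harness with a
first-PC (PLAGE-style) baseline. See `docs/methods.md` for the full model
description and design choices.

## Worked example

```python
from reset import (SimulationDesign, simulate_counts, log_normalize,
                   ResetParams, reset_randomized)
from reset.evaluate import auc

# 2,000 cells x 500 genes; five disjoint 50-gene sets; the first set's
# genes carry 3x inflated, rho=0.4 correlated counts in 200 cells.
ds = simulate_counts(SimulationDesign(design="block", n_sets=5,
                                      correlation=0.4, seed=7))
normalized = log_normalize(ds.counts)
scores = reset_randomized(normalized, ds.annotation,
                          ResetParams(b=20, k=10, seed=7))
print(scores.overall_frame().to_string(index=False))
print("sample-level AUC (set1 vs informative cells):",
      round(auc(scores.S[:, 0], ds.informative_cells), 3))
```

prints

```
 set    score
set1 0.123838
set2 0.039913
set3 0.034047
set4 0.027628
set5 0.040083
sample-level AUC (set1 vs informative cells): 0.879
```

The planted set (`set1`) receives an overall score ~3-4x the null sets',
and its per-cell scores separate the 200 informative cells from the rest
with AUC 0.88.

The same pipeline is available from the shell:

```sh
reset simulate --design block --rho 0.4 --seed 7 --out-dir sim/
reset score --matrix sim/ --genesets sim/sets.gmt --b 20 --k 10 \
      --seed 7 --out-dir scores/
reset evaluate --config grid.yaml --out-dir evaluation/
```

`score` writes `S.tsv`, `v.tsv` and a `run_metadata.json` with all
resolved parameters, per-set effective ranks and degeneracy flags.

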