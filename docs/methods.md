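# Methods

## Model

The scoring method treats a gene set as good if an orthonormal basis built
from the set's (centered) expression columns can reconstruct the dominant
structure of the whole expression matrix. Three variants are implemented,
in increasing order of realism:

- `reset_simplistic` reconstructs the full matrix **X** from a full-width
  QR basis of each set's columns. It is transparent and serves as the
  reference implementation in tests, but its null scores grow strongly
  with set size (the reconstruction rank equals the set size) and it is
  dominated by noise whenever the biological rank of **X** is low.
- `reset_reduced` first projects the column-centered matrix onto its top
  *b* principal components (exact SVD) and reconstructs that projection
  **P** from a rank-*k* column-pivoted-QR basis of each set. Working on
  **P** rather than **X** suppresses noise beyond the biological rank and
  removes the gross set-size dependence of the null scores.
- `reset_randomized` is the production variant: the SVD is replaced by a
  randomized truncated SVD and, for sets larger than `random_threshold`,
  the per-set basis by a randomized rangefinder. It is bit-reproducible
  given a seed, and with an exact SVD plus a threshold at or above the
  largest set size it reproduces `reset_reduced` exactly.

Scores are log2 norm ratios of the projection and its reconstruction
error, overall (Frobenius) and per sample (row-wise, Euclidean or L1).
The optional per-variable adjustment divides a set's scores by
l_i / l̄ so that, in a non-null setting, a small set of purely informative
genes outranks a superset padded with noise genes; sets of exactly mean
size are unchanged. The adjustment deliberately breaks the null
equivalence of scores across set sizes.

Assumptions: the input is already quality-controlled and normalized
(the package provides per-cell log-normalization,
`log(1 + count * scale_factor / cell_total)`, for raw counts); genes are
columns; the biological signal has low effective rank; set membership is
binary.

### Basis construction and centering

Per-set bases are always built from *centered* set columns (the centered
matrix's columns in the standard path; freshly centered dense sub-matrices
in the delayed path). Centering the sub-matrix makes the per-set basis
consistent with the centered projection it reconstructs; building bases
from raw columns instead wastes basis directions on the all-ones mean
component and measurably degrades separation.

The deterministic basis is a column-pivoted QR truncated at
min(k, numerical rank) columns, with the numerical rank taken at the
usual `eps * max(shape)` relative tolerance on the pivoted diagonal of R.
The randomized basis sketches with a standard Gaussian test matrix at
width min(k + d, l, n), applies q power iterations with QR
re-orthonormalization after every product, and rotates the sketch basis
onto the top singular directions of the projected matrix before
truncating to k columns, so the retained directions are ordered by
captured variance.

## Parameters

| parameter | default | meaning |
|---|---|---|
| b | 20 | rank of the PC projection; should approximate the biological rank of **X** |
| k | 10 | per-set reconstruction rank |
| d (`oversample`) | 10 | extra sketch columns beyond the target rank |
| q (`power_iters`) | 2 | power iterations sharpening the sketch spectrum |
| `random_threshold` | 3·k | sets strictly larger use the randomized basis; randomization only pays off once l ≳ 3k |
| `per_var` | off | divide scores by l_i / l̄ |
| `center` / `scale` | on / off | column centering and sample-SD (n−1) scaling before the projection |
| `norm_type` | L2 | row norm for sample scores (overall scores always Frobenius) |

Large *b* folds noise components into the scores; small *b* measures
reconstruction on only part of the signal. Large *k* lets small sets
reconstruct noise; small *k* deflates large sets. Defaults follow common
randomized-SVD practice (d = 10, q = 2) and a rank-10/rank-20
representation appropriate for the simulated data scale; all are exposed.

## Numerical choices

- **Degenerate reconstructions.** The algorithm's log ratio is undefined
  when **E** = 0 (a set that spans the projection exactly). Error norms
  are floored at `eps * max(P.shape)` times the matching norm of **P** —
  the standard numerical-rank tolerance scaling — capping scores near 50
  and setting a degeneracy flag instead of returning infinity.
- **Zero-norm rows.** A sample whose projection row is exactly zero
  scores 0: the data carry no evidence either way.
- **Negative row ratios.** The projection is orthogonal column-wise, so
  the Frobenius norm of **E** never exceeds that of **P** and overall
  scores are ≥ 0; individual *rows* of **E** can, however, exceed the
  corresponding rows of **P**. Sample scores are clamped at 0 — a
  worse-than-nothing reconstruction of one sample is treated as no
  evidence, keeping all scores non-negative and comparable.
- **Sparse input.** With `center=False` on sparse input the SVD runs on
  the uncentered matrix, the PC projection is centered after the fact,
  and only per-set sub-matrices are densified. These scores differ from
  the pre-centered path whenever column means are nonzero; that is the
  documented price of never densifying the matrix.
- **Gene matching.** GMT genes absent from the matrix are dropped
  (exact, case-sensitive match); sets outside the size filter are removed
  with a logged count; duplicated matrix gene ids keep the first column.
  l̄ is computed over the sets actually evaluated.
- **Determinism.** One user seed feeds a single generator consumed in
  documented order (projection sketch first, then per-set sketches in
  input order), so whole runs are bit-reproducible.

## Synthetic data

The simulator emulates droplet scRNA-seq counts: independent negative
binomials with fixed dispersion θ (variance μ + μ²/θ, default θ = 1) and
per-gene means from a shifted exponential, mean_j = base + Exp(rate),
with defaults of 2,000 cells, 500 genes, 50-gene sets, 200 informative
cells, 3× mean inflation, pairwise correlation 0.2, unit base mean and
unit rate. A planted rectangle of informative genes × informative cells
receives inflated means and exchangeable pairwise correlation in four
designs: **block** (one set, a cell subset), **complex** (the first set's
first half correlated across *all* cells with no inflation — a dominant
but uninformative component — and its second half carrying the
informative block, so the label signal sits on the sub-matrix's second
PC), **self_contained** (every gene in one set), and **competitive**
(every cell informative for the first of five disjoint equal sets).

Correlation is induced by a single-factor Gaussian copula. Because the NB
quantile map shrinks correlation, the latent Gaussian correlation is
calibrated by a seeded Monte-Carlo bisection (cached per mean/dispersion/
target) so the *realized count-scale Pearson correlation* matches the
request to ~0.01; quantiles are evaluated exactly via precomputed CDF
tables.

What the generator does not emulate: library-size variation between
cells, gene-length or capture biases, batch structure, zero inflation
beyond the NB, and realistic co-expression networks (correlation is
exchangeable within one block). Passing benchmarks on these data
therefore demonstrate sensitivity to planted mean/correlation structure
under idealized noise, not performance on any real tissue.

Two properties of this generator are worth knowing when reading results:

- Log-normalization does not fully cancel a mean inflation applied to all
  genes of a cell: counts are discrete, so higher means change the zero
  fraction and the log1p curvature even at a fixed count share. In the
  self-contained design the classification AUC therefore still rises
  with inflation (≈0.86 → 0.96 across 1.5×–6× at correlation 0.2) unless
  the correlation is strong enough to saturate the AUC.
- In the competitive design the only per-cell signal surviving
  normalization and centering is the cell's loading on the single
  correlation factor, so pooled (cell × set) AUC plateaus around
  0.66–0.76 at correlations 0.2–0.4 — replacing the bases with oracle
  SVD bases does not raise this — while the overall scores **v** identify
  the enriched set essentially perfectly.

## Evaluation

AUC is the Mann–Whitney statistic with midrank ties. For block-style
designs the enriched set's per-cell scores are compared against the
informative-cell labels; for the competitive design (all cells
informative) every (cell, set) score is pooled with the enriched set's
scores labeled positive — a design decision, since a per-cell paired
comparison gives nearly identical numbers. The overall-score experiment
pools **v** across replicates (each contributes one positive and m − 1
negatives), the only well-defined estimator when a replicate has a single
positive. Replicates draw independent seeds derived from one experiment
seed; summaries report mean AUC ± SEM across replicates.

The first-PC baseline column-standardizes each set's sub-matrix and
projects samples onto its first principal component. The PC's sign is
arbitrary, so its AUC can fall below 0.5; values are reported as-is.

## Known limitations

- Null overall scores retain a mild set-size dependence (~15–20% higher
  means for 80- vs 20-gene sets under iid noise): a larger set's dominant
  directions align more with the global PCs even under the null. The
  reduced-rank construction removes the *gross* dependence (several-fold
  under the full-width variant) but not this residual; treat overall
  scores for very differently sized sets with care, or use `per_var`.
- Reported problem sizes for the built-in benchmarks are scaled down
  (typically 20 replicates at 2,000 × 500) as the package's own default;
  replicate counts are parameters everywhere.
- No p-values are attached to scores; the method is a scoring transform,
  not a test.
- The pivoted QR is computed full-width and truncated; a lazily truncated
  pivoted QR would be faster for very wide sets but numerically
  equivalent.
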