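# Methods

## The model

scbfp imputes dropout zeros in a single-cell expression matrix
X ∈ ℝ^{G×C} (G genes, C cells) in two sequential graph-smoothing steps.

**Step 1 — gene-wise feature propagation (warm-up).**
A cosine-similarity kNN graph is built over genes, self-loops are added,
and the adjacency is symmetrically normalized, Ã = D^{-1/2}(A+I)D^{-1/2}.
Writing Δ = I − Ã for the Laplacian, each cell's column is treated as a
function on the gene graph and evolved by the discrete heat flow

    X^{(i+1)} = X^{(i)} − h·Δ X^{(i)},   observed entries re-imposed each step,

which for step size h = 1 reduces to multiply-and-clamp,
X^{(i+1)} = Ã X^{(i)} with X_𝒩 reset to its original values (𝒩 = indices
that were non-zero in the input, 𝒵 = the zeros).  The flow minimizes the
Dirichlet energy ½ Σ_c X_{·,c}ᵀ Δ X_{·,c} subject to the clamped boundary.
Because Ã's zero-block submatrix Ã_zz has spectral radius < 1 whenever a
graph component contains at least one observed gene, the iteration
converges, and its fixed point is the harmonic extension

    x_z = (I − Ã_zz)^{-1} Ã_zn x_n = −Δ_zz^{-1} Ã_zn x_n.

The package also implements this direct solve (`closed_form_impute`); it is
cubic in |𝒵| and exists as the oracle against which the iterative path is
tested, never as the production path.  Observed counts are untouched by
construction — the warm-up only fills zeros.

**Step 2 — cell-wise diffusion.**
The warmed matrix is transposed to cell×gene and a *new* cosine-kNN graph
is built over cells from it — the "enhanced" graph, since imputed zeros make
cosine neighborhoods far less dropout-biased than on the raw matrix.  Its
adjacency is random-walk normalized (Ã^cell = D^{-1}(A+I)), so each step

    X'^{(j+1)} = Ã^cell X'^{(j)}

replaces every cell's profile by a convex combination of its neighborhood;
random-walk (rather than symmetric) normalization lets sparsely captured
cells be enriched by their well-covered neighbors.  There is no clamping:
non-zeros are denoised too.  On a connected graph this iteration's only
fixed points are constant-per-column profiles (the stationary projection),
so J must stay small; variance collapse is geometric in the spectral gap.

## Parameters

| name | default | meaning |
|---|---|---|
| `k_gene`, `k_cell` | 20 | neighbors per node; ≳10 typically makes the graphs connected, which the convergence argument assumes |
| `max_iter_gene` | 40 | warm-up iteration cap; columns also stop early at `tol` |
| `tol` | 1e-6 | per-column max-absolute-change stopping threshold (change per entry, expression units) |
| `iter_cell` (J) | 2 | diffusion steps; >10 logs an oversmoothing warning |
| `h` | 1.0 | Euler step size; only the generalized path uses ≠1 |
| `batch_size` | None | propagate this many columns at a time; output is bitwise identical, only peak memory changes |
| `self_loops` | True | added to both graphs before normalization |
| `weighted_edges` | False | binary kNN edges by default; optionally cosine-weighted |

Stopping on tolerance *per column* (freezing converged columns) is what
makes batched and unbatched propagation exactly equal: columns never
interact through Ã, so each column's trajectory and stopping iteration are
independent of how columns are grouped.

Zeros are initialized at 0, which makes the zero-iteration output equal the
input; columns in a graph component with no observed value stay 0 rather
than erroring.

## Graph construction choices

Exact brute-force cosine kNN (full similarity matrix, blocked over row
chunks above 20 000 nodes with identical results); no approximate indices,
so results are reproducible bit-for-bit.  Ties are broken by ascending node
index; the cosine similarity of an all-zero row is defined as 0 to every
node (such rows still emit k edges via the tie-break).  Directed picks are
union-symmetrized — an undirected edge exists if either endpoint picks the
other — which guarantees minimum degree k and avoids isolated nodes;
mutual-kNN is available but not the default.  Edges are binary: the
normalization already encodes degree structure, and binary weights keep the
operator's spectral properties transparent.

## Synthetic data

`generate_counts` draws per-gene log-normal baseline means; each cell type
shifts a random `de_fraction` of genes by ±`de_log_fold` (natural log);
cells get log-normal size factors (mean 1, sd `size_factor_sd`); counts are
gamma-Poisson (negative binomial with size `dispersion`: var = μ + μ²/θ);
dropout then zeroes non-zero entries either uniformly at `dropout_rate` or
with probability exp(−λμ), λ calibrated by bisection so the realized rate
matches the request (intensity-dependent mode).  The generator reproduces
the features the method exploits — cluster-wise cell similarity, gene
co-expression, overdispersion, library-size variation, dropout — and omits
amplification bias, batch effects, doublets, and kinetic bursting.  Passing
tests on it shows the algorithm behaves as designed under its own model
assumptions; it is not evidence about any particular real tissue.

Default dimensions follow the simulated benchmark regime of 3000 cells ×
2000 genes with five types.  The rare-type preset (one type at 2%
prevalence) exercises the class-imbalance path that macro-F1 measures.

## Benchmark protocol

The recovery benchmark generates counts *without* generative dropout,
library-normalizes each cell to the median total and applies log1p (zeros
are fixed points of both transforms, so the observed/zero partition is
unchanged), masks 40% of the non-zero entries uniformly at random, imputes
with default settings, and scores median L1 and RMSE at the masked
coordinates only, against a leave-as-zero baseline.  Masking is the dropout
process under study; adding generative dropout on top would conflate the
two corruption sources.  Imputation runs on log-normalized expression
because cosine similarity on raw counts is dominated by magnitude noise;
the pipeline itself applies no preprocessing (`preprocess` is a separate,
optional step), so users control this explicitly.  Clustering quality is
k-means (10 seeded restarts) on log1p + 50-component PCA, scored by ARI,
NMI, clustering accuracy under the optimal one-to-one Hungarian
cluster-to-class assignment, and macro-F1 under that same assignment —
predicted clusters left unmatched count entirely as errors.  Note that
one-to-one CA is *not* bounded below by the majority-class prevalence (that
bound belongs to many-to-one majority voting); a single predicted cluster
scores exactly the prevalence.

The benchmark fixture used throughout the test suite and the acceptance
script is 500 cells × 300 genes, four types with one at 2% prevalence,
`de_log_fold` 1.5 — small enough to run in seconds on one CPU while keeping
all the structural features above.  The memory-scaling check uses a
2000-gene × 8000-cell sparse matrix: batched propagation's peak allocation
stays near one dense-output footprint while the unbatched path needs
several, demonstrating that memory grows with `batch_size × n_genes`, not
`n_genes × n_cells`.

## Numerical notes and limitations

- All propagation is double precision; the final clamp restores the stored
  original values bitwise, not re-thresholded ones.
- The closed-form solve refuses components with no observed node
  (singular system) and names the component.
- Oversmoothing: the variance-collapse rate is governed by the cell graph's
  second eigenvalue; strongly clustered graphs collapse slowly *between*
  clusters, which is precisely why 1–2 diffusion steps help and 200 destroy
  structure.
- The imputed matrix is dense by construction; memory for the output itself
  is irreducible at G×C doubles.
- True zeros are imputed too (the method cannot distinguish a biological
  zero from a dropout); empirically they receive systematically smaller
  values than masked dropouts, but they are not returned as zero.
- No GPU path: batching addresses memory, and correctness is CPU-testable.
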