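# scbfp

Graph feature-propagation imputation and denoising for single-cell
RNA-seq expression matrices.

scRNA-seq count matrices are riddled with *dropout* zeros — failed mRNA
capture, not true absence of expression — which corrupts everything
downstream, from neighbor graphs to clustering.  scbfp fills and denoises
such a matrix in two deterministic, training-free steps:

1. **Gene-wise feature propagation (warm-up).**  On a cosine-kNN
   gene–gene graph with symmetrically normalized adjacency
   Ã = D^{-1/2}(A+I)D^{-1/2}, iterate X ← ÃX while re-imposing the
   observed (non-zero) entries after every step.  This minimizes the
   Dirichlet energy ½ Σ_c X_{·,c}ᵀ(I−Ã)X_{·,c} with the observations as a
   clamped boundary, so every zero converges to the harmonic extension of
   its gene's observed neighbors: x_z = (I − Ã_zz)^{-1} Ã_zn x_n.
   Observed counts come out bit-identical.
2. **Cell-wise diffusion.**  Transpose, rebuild a cosine-kNN cell–cell
   graph from the warmed matrix (imputed zeros make neighbor detection far
   more reliable), and apply the row-stochastic operator X' ← D^{-1}(A+I)X'
   a small number of times (default 2) with no clamping, denoising all
   entries toward their cell-neighborhood averages.

Columns are independent under X ← ÃX, so the warm-up runs feature-batch by
feature-batch with bitwise-identical output — peak memory scales with
`batch_size × n_genes` instead of the full matrix, which is what makes the
method practical on atlas-scale data.

Intended users: anyone preparing an scRNA-seq expression matrix for
clustering or visualization who wants a fast, deterministic, parameter-light
imputer; and method developers who need its synthetic benchmark
(clustered negative-binomial counts with controllable dropout, recovery and
clustering metrics) to evaluate imputation methods.

## Worked example

```python
import numpy as np
from scbfp import (ScBFPConfig, SyntheticSpec, generate_counts, mask_nonzeros,
                   rare_type_proportions, run_scbfp, recovery_error,
                   cluster_cells, clustering_scores)
from scbfp.io import preprocess

spec = SyntheticSpec(n_cells=500, n_genes=300, n_types=4,
                     type_proportions=rare_type_proportions(4, 0.02),
                     de_log_fold=1.5, seed=0)
counts, labels, _ = generate_counts(spec)
expr = preprocess(counts)                      # library-normalize + log1p
exp = mask_nonzeros(expr, rate=0.4, seed=0)    # hide 40% of non-zeros

imputed, report = run_scbfp(exp.corrupted, ScBFPConfig())
rec = recovery_error(exp, imputed)
base = recovery_error(exp, exp.corrupted)
ari = clustering_scores(cluster_cells(imputed, 4, seed=0), labels).ari
ari0 = clustering_scores(cluster_cells(exp.corrupted, 4, seed=0), labels).ari

print(f"median L1  scbfp {rec.median_l1:.3f}  vs zeros {base.median_l1:.3f}")
print(f"RMSE       scbfp {rec.rmse:.3f}  vs zeros {base.rmse:.3f}")
print(f"ARI        imputed {ari:.3f}  vs corrupted {ari0:.3f}")
print("gene graph connected:", report["gene_graph"]["connected"],
      "| warm-up iterations:", report["n_iter_gene"])
```

prints

```
median L1  scbfp 0.321  vs zeros 1.081
RMSE       scbfp 0.488  vs zeros 1.432
ARI        imputed 0.976  vs corrupted 0.820
gene graph connected: True | warm-up iterations: 40
```

Reading: at the masked coordinates the imputed values sit a median of 0.32
log-expression units from the hidden truth, versus 1.08 if the dropouts are
left at zero — a threefold error reduction — and k-means clustering of the
imputed matrix recovers the true cell types almost perfectly (ARI 0.98)
where the corrupted matrix does not (0.82).

The same pipeline is available as a scikit-learn transformer
(`ScBFPImputer().fit_transform(X)` on a cell × gene matrix, composable with
sklearn pipelines) and as a CLI:

```sh
scbfp impute counts.csv imputed.csv --k-gene 20 --k-cell 20
scbfp benchmark --sim-spec spec.json --rates 0.1,0.4 --seeds 0,1 --out bench.tsv
scbfp simulate spec.json outdir/
```

`impute` accepts 10x-style MTX directories, CSV/TSV and `.h5ad`, and writes
the imputed cell × gene matrix plus a JSON manifest (config echo, input
checksum, graph connectivity, residuals) sufficient to re-run identically.

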