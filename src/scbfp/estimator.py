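"""scikit-learn estimator interface to the two-step imputer.

:class:`ScBFPImputer` follows the transformer contract: ``X`` is the
cell x gene matrix (samples are cells, features are genes, dense or
sparse), ``fit_transform(X)`` returns the dense imputed cell x gene
matrix.  The method is transductive — both graphs are built from the data
being imputed — so ``transform`` on a new matrix simply runs the full
pipeline on it with the fitted parameters.

Pipeline (all deterministic):

1. build a cosine-kNN gene-gene graph from the raw matrix, symmetrically
   normalized with self-loops;
2. clamped feature propagation fills the zeros and leaves observed counts
   untouched, giving the warmed-up matrix;
3. rebuild a cosine-kNN cell-cell graph from the warmed-up matrix
   (the enhanced graph), random-walk normalized;
4. a few unclamped diffusion steps smooth every entry over its cell
   neighborhood.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import graph as graph_mod
from .diffusion import ScBFPConfig, diffuse
from .propagation import ObservedMask, propagate_batched


class ScBFPImputer(TransformerMixin, BaseEstimator):
    """Two-step graph feature-propagation imputer for scRNA-seq matrices.

    Parameters
    ----------
    k_gene, k_cell:
        Neighbors per node for the gene-gene and cell-cell graphs.  Values
        above ~10 typically make each graph connected, which the warm-up's
        convergence guarantee relies on.
    max_iter_gene:
        Cap on warm-up propagation iterations (columns also stop early once
        their largest change drops below ``tol``).
    iter_cell:
        Number of unclamped diffusion steps; kept small because repeated
        averaging collapses gene columns toward a constant profile.
    h:
        Euler step size of the warm-up scheme; 1.0 gives the simplified
        multiply-and-clamp update.
    batch_size:
        Propagate this many cells' columns at a time (None = all at once);
        results are bitwise identical, only peak memory changes.
    weighted_edges:
        Carry cosine similarities as edge weights instead of binary edges.
    self_loops:
        Add self-loops before normalizing either graph.
    seed:
        Recorded in the run report; the pipeline itself is deterministic.

    Attributes
    ----------
    imputed_ : ndarray
        Dense imputed cell x gene matrix from :meth:`fit`.
    warmed_ : ndarray
        Gene x cell matrix after clamped propagation only.
    gene_graph_, cell_graph_ : KNNGraph
    n_iter_gene_ : int
    residual_gene_ : float
    report_ : dict
        Config echo, connectivity of both graphs, iteration counts and
        residuals — enough to re-run identically.
    """

    def __init__(
        self,
        k_gene: int = 20,
        k_cell: int = 20,
        max_iter_gene: int = 40,
        iter_cell: int = 2,
        tol: float = 1e-6,
        h: float = 1.0,
        batch_size: int | None = None,
        weighted_edges: bool = False,
        self_loops: bool = True,
        seed: int = 0,
    ) -> None:
        self.k_gene = k_gene
        self.k_cell = k_cell
        self.max_iter_gene = max_iter_gene
        self.iter_cell = iter_cell
        self.tol = tol
        self.h = h
        self.batch_size = batch_size
        self.weighted_edges = weighted_edges
        self.self_loops = self_loops
        self.seed = seed

    # -- config bridge ----------------------------------------------------
    @classmethod
    def from_config(cls, cfg: ScBFPConfig) -> "ScBFPImputer":
        return cls(
            k_gene=cfg.k_gene,
            k_cell=cfg.k_cell,
            max_iter_gene=cfg.max_iter_gene,
            iter_cell=cfg.iter_cell,
            tol=cfg.tol,
            h=cfg.h,
            batch_size=cfg.batch_size,
            weighted_edges=cfg.weighted_edges,
            self_loops=cfg.self_loops,
            seed=cfg.seed,
        )

    def to_config(self) -> ScBFPConfig:
        cfg = ScBFPConfig(**{k: v for k, v in self.get_params().items()})
        cfg.validate()
        return cfg

    # -- validation -------------------------------------------------------
    def _validate(self, X):
        self.to_config()
        if sp.issparse(X):
            X = X.tocsr().astype(float)
            data = X.data
        else:
            X = np.asarray(X, dtype=float)
            data = X
        if X.ndim != 2:
            raise ValueError("X must be a 2-D cell x gene matrix")
        if data.size and not np.all(np.isfinite(data)):
            raise ValueError("X contains non-finite entries")
        if data.size and data.min() < 0:
            raise ValueError("X contains negative entries")
        nnz = X.nnz if sp.issparse(X) else int(np.count_nonzero(X))
        if nnz == 0:
            raise ValueError("X is all zero; nothing to impute a graph from")
        n_cells, n_genes = X.shape
        if not 1 <= self.k_gene <= n_genes - 1:
            raise ValueError(f"k_gene={self.k_gene} must be in [1, n_genes-1]")
        if not 1 <= self.k_cell <= n_cells - 1:
            raise ValueError(f"k_cell={self.k_cell} must be in [1, n_cells-1]")
        return X

    # -- core -------------------------------------------------------------
    def _run(self, X):
        """Full pipeline on a validated cell x gene matrix."""
        xg = X.T  # gene x cell; rows are graph nodes for the warm-up
        mask = ObservedMask.from_matrix(xg)

        gene_graph = graph_mod.cosine_knn(
            xg, self.k_gene, weighted=self.weighted_edges
        )
        op_gene = graph_mod.normalize(
            gene_graph, graph_mod.SYMMETRIC, add_self_loops=self.self_loops
        )
        warmed, n_iter, residual = propagate_batched(
            xg,
            op_gene,
            mask,
            max_iter=self.max_iter_gene,
            tol=self.tol,
            batch_size=self.batch_size,
            h=self.h,
        )

        xw = warmed.T  # cell x gene; the enhanced cell graph is built from it
        cell_graph = graph_mod.cosine_knn(
            xw, self.k_cell, weighted=self.weighted_edges
        )
        op_cell = graph_mod.normalize(
            cell_graph, graph_mod.RANDOM_WALK, add_self_loops=self.self_loops
        )
        denoised, diag = diffuse(xw, op_cell, self.iter_cell)

        gene_conn = graph_mod.connectivity_report(gene_graph)
        cell_conn = graph_mod.connectivity_report(cell_graph)
        report = {
            "config": self.get_params(),
            "seed": self.seed,
            "n_genes": X.shape[1],
            "n_cells": X.shape[0],
            "gene_graph": {"n_components": gene_conn[0], "connected": gene_conn[1]},
            "cell_graph": {"n_components": cell_conn[0], "connected": cell_conn[1]},
            "n_iter_gene": int(n_iter),
            "residual_gene": float(residual),
            "n_iter_cell": diag.n_iter,
            "diffusion_change_norms": diag.change_norms,
        }
        return {
            "warmed": warmed,
            "imputed": denoised,
            "gene_graph": gene_graph,
            "cell_graph": cell_graph,
            "op_gene": op_gene,
            "op_cell": op_cell,
            "n_iter_gene": int(n_iter),
            "residual_gene": float(residual),
            "diagnostics": diag,
            "report": report,
        }

    def fit(self, X, y=None):
        """Run the pipeline on ``X`` (cell x gene) and store the results."""
        X = self._validate(X)
        state = self._run(X)
        self.n_features_in_ = X.shape[1]
        self.warmed_ = state["warmed"]
        self.imputed_ = state["imputed"]
        self.gene_graph_ = state["gene_graph"]
        self.cell_graph_ = state["cell_graph"]
        self.gene_operator_ = state["op_gene"]
        self.cell_operator_ = state["op_cell"]
        self.n_iter_gene_ = state["n_iter_gene"]
        self.residual_gene_ = state["residual_gene"]
        self.diffusion_diagnostics_ = state["diagnostics"]
        self.report_ = state["report"]
        return self

    def transform(self, X):
        """Impute ``X``: the pipeline is transductive, so it runs in full.

        Deterministic, hence ``fit(X).transform(X)`` equals
        ``fit_transform(X)`` exactly.
        """
        check_is_fitted(self, "imputed_")
        X = self._validate(X)
        return self._run(X)["imputed"]

    def fit_transform(self, X, y=None):
        return self.fit(X).imputed_
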