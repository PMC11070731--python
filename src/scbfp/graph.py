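"""Cosine-similarity kNN graphs and normalized propagation operators.

The imputer builds two graphs: a gene-gene graph over the rows of the raw
matrix (symmetrically normalized, with self-loops) and a cell-cell graph
over the rows of the warmed-up matrix (random-walk normalized, so each
diffusion step averages a cell's profile over its neighborhood; spreading
mass *from* well-covered, high-degree cells into sparsely captured ones is
the point of this choice).

Construction is exact and deterministic: the full cosine-similarity matrix
is scanned (blocked over row chunks above ``BRUTE_FORCE_LIMIT`` nodes, with
bitwise-identical results), ties are broken by ascending node index, and the
cosine similarity of an all-zero row is defined as 0 against every node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

#: above this many nodes the similarity matrix is computed in row blocks
BRUTE_FORCE_LIMIT = 20_000

SYMMETRIC = "symmetric"
RANDOM_WALK = "random_walk"


class IsolatedNodeError(ValueError):
    """A node with degree zero cannot be normalized without a self-loop."""


@dataclass
class KNNGraph:
    """Binary, symmetric kNN adjacency (zero diagonal)."""

    adjacency: sp.csr_matrix
    k: int
    self_loops_added: bool = False

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()


@dataclass
class NormalizedAdjacency:
    """A normalized propagation operator Ã with its Laplacian Δ = I − Ã."""

    operator: sp.csr_matrix
    mode: str

    @property
    def n_nodes(self) -> int:
        return self.operator.shape[0]

    def laplacian(self) -> sp.csr_matrix:
        return (sp.identity(self.n_nodes, format="csr") - self.operator).tocsr()


def _unit_rows(rows):
    """L2-normalize rows; all-zero rows stay zero (cosine defined as 0).

    Sparse input stays sparse so graph construction never materializes a
    dense copy of a large expression matrix.
    """
    if sp.issparse(rows):
        norms = np.sqrt(np.asarray(rows.multiply(rows).sum(axis=1)).ravel())
        safe = np.where(norms > 0, norms, 1.0)
        return (sp.diags(1.0 / safe) @ rows).tocsr()
    norms = np.linalg.norm(rows, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    return rows / safe[:, None]


def _topk_indices(sims: np.ndarray, row_offset: int, k: int) -> np.ndarray:
    """Per-row top-k column indices, self excluded, ties by ascending index.

    ``sims`` is a (block x n) similarity slab whose rows correspond to global
    node ids ``row_offset .. row_offset+block-1``.
    """
    block, n = sims.shape
    sims = sims.copy()
    rows_local = np.arange(block)
    self_cols = rows_local + row_offset
    sims[rows_local, self_cols] = -np.inf
    # stable argsort of -sims gives descending similarity, ascending index on ties
    order = np.argsort(-sims, axis=1, kind="stable")
    return order[:, :k]


def cosine_knn(
    rows, k: int, symmetrize: str = "union", weighted: bool = False
) -> KNNGraph:
    """Build a kNN graph over the rows of ``rows`` by cosine similarity.

    Each node points at its ``k`` most similar other nodes; directed edges
    are combined by ``union`` (edge if either endpoint picks the other) or
    ``mutual`` (edge only if both do).  Union is the default: it guarantees
    minimum degree ``k`` and avoids isolated nodes.  Edges are binary unless
    ``weighted`` is set, in which case they carry the cosine similarity
    (clipped at 0).
    """
    sparse_in = sp.issparse(rows)
    if sparse_in:
        rows = rows.tocsr().astype(float)
    else:
        rows = np.asarray(rows, dtype=float)
    n, d = rows.shape
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if d == 0:
        raise ValueError("rows have zero dimensions")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k={k} must be in [1, n-1] with n={n}")
    if symmetrize not in ("union", "mutual"):
        raise ValueError(f"unknown symmetrize mode {symmetrize!r}")

    unit = _unit_rows(rows)

    indptr = [0]
    cols = []
    weights = []
    if n <= BRUTE_FORCE_LIMIT:
        blocks = [(0, n)]
    else:
        step = max(1, int(2e8 // max(n, 1)))  # ~1.6 GB slab ceiling
        blocks = [(s, min(s + step, n)) for s in range(0, n, step)]
    for start, stop in blocks:
        sims = unit[start:stop] @ unit.T
        if sp.issparse(sims):
            sims = np.asarray(sims.todense())
        picked = _topk_indices(sims, start, k)
        for r in range(stop - start):
            idx = np.sort(picked[r])
            cols.append(idx)
            if weighted:
                weights.append(np.maximum(sims[r, idx], 0.0))
            indptr.append(indptr[-1] + k)
    data = (
        np.concatenate(weights) if weighted else np.ones(indptr[-1])
    )
    directed = sp.csr_matrix(
        (data, np.concatenate(cols), np.asarray(indptr)), shape=(n, n)
    )

    if symmetrize == "union":
        sym = directed.maximum(directed.T)
    else:
        sym = directed.minimum(directed.T)
    if not weighted:
        sym.data[:] = 1.0
    sym.setdiag(0)
    sym.eliminate_zeros()
    return KNNGraph(sym.tocsr(), k=k)


def normalize(
    g: KNNGraph, mode: str, add_self_loops: bool = True
) -> NormalizedAdjacency:
    """Normalize the adjacency into a propagation operator.

    ``symmetric`` returns D^{-1/2} A' D^{-1/2} (spectrum in [-1, 1]);
    ``random_walk`` returns D^{-1} A' (row-stochastic).  ``A' = A + I`` when
    self-loops are requested; D is the degree matrix of A'.
    """
    if mode not in (SYMMETRIC, RANDOM_WALK):
        raise ValueError(f"unknown normalization mode {mode!r}")
    a = g.adjacency.copy().astype(float)
    if add_self_loops:
        a = (a + sp.identity(g.n_nodes, format="csr")).tocsr()
    deg = np.asarray(a.sum(axis=1)).ravel()
    isolated = np.flatnonzero(deg == 0)
    if isolated.size:
        raise IsolatedNodeError(
            f"node(s) {isolated[:10].tolist()} have degree 0; "
            "add self-loops or increase k"
        )
    if mode == SYMMETRIC:
        d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
        op = (d_inv_sqrt @ a @ d_inv_sqrt).tocsr()
    else:
        op = (sp.diags(1.0 / deg) @ a).tocsr()
    return NormalizedAdjacency(op, mode=mode)


def connectivity_report(g: KNNGraph) -> tuple[int, bool]:
    """Connected-component count of the symmetrized graph.

    Convergence of clamped propagation needs at least one observed node per
    component; empirically a single component is reached once k exceeds ~10.
    """
    n_comp, _ = connected_components(g.adjacency, directed=False)
    return int(n_comp), bool(n_comp == 1)


def export_edge_list(g: KNNGraph, path) -> None:
    """Write the undirected edge list as a two-column TSV (i < j)."""
    coo = sp.triu(g.adjacency, k=1).tocoo()
    with open(path, "w") as fh:
        for i, j in zip(coo.row, coo.col):
            fh.write(f"{i}\t{j}\n")
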