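"""Cell-wise random-walk diffusion and the full two-step pipeline driver.

After the warm-up, the matrix is transposed to cell x gene and a fresh
cosine-kNN cell-cell graph is built from it (the "enhanced" graph: the
imputed zeros make neighbor detection far less noisy than on the raw
dropout-ridden matrix).  Diffusion then applies the row-stochastic operator
X' ← Ã X' a small fixed number of times with no clamping, so both zeros and
observed entries are smoothed toward their neighborhood averages.

Unlike the clamped warm-up, this flow has a degenerate limit: on a connected
graph repeated averaging collapses every gene column toward a constant
profile (the stationary projection), which is why the default number of
steps is small (J = 2) and large J triggers an oversmoothing warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graph import NormalizedAdjacency, RANDOM_WALK

logger = logging.getLogger(__name__)

OVERSMOOTHING_WARN_STEPS = 10


@dataclass
class ScBFPConfig:
    """Tunable parameters of the two-step imputer.

    ``h`` is the Euler step size of the warm-up scheme; it is 1 in the
    simplified update and exposed only for the generalized path.
    """

    k_gene: int = 20
    k_cell: int = 20
    h: float = 1.0
    max_iter_gene: int = 40
    iter_cell: int = 2
    tol: float = 1e-6
    batch_size: int | None = None
    seed: int = 0
    weighted_edges: bool = False
    self_loops: bool = True

    def validate(self) -> None:
        if self.k_gene < 1 or self.k_cell < 1:
            raise ValueError("k_gene and k_cell must be >= 1")
        if self.max_iter_gene < 0 or self.iter_cell < 0:
            raise ValueError("iteration counts must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be >= 1 or None")


@dataclass
class DiffusionDiagnostics:
    """Per-iteration change norms and the optional stationary distribution."""

    n_iter: int
    change_norms: list = field(default_factory=list)
    stationary_distribution: np.ndarray | None = None


def diffuse(
    xw, op: NormalizedAdjacency, n_steps: int
) -> tuple[np.ndarray, DiffusionDiagnostics]:
    """Apply X' ← Ã^cell X' exactly ``n_steps`` times, with no clamping.

    ``xw`` is the warmed cell x gene matrix (rows are cells, matching the
    operator); each output entry is a convex combination of input entries
    in its graph neighborhood.  Records the max-absolute change per step.
    """
    if n_steps < 0:
        raise ValueError("number of diffusion steps must be >= 0")
    if op.mode != RANDOM_WALK:
        raise ValueError("cell-wise diffusion expects a random-walk operator")
    if sp.issparse(xw):
        xw = np.asarray(xw.todense(), dtype=float)
    x = np.array(xw, dtype=float)
    if x.shape[0] != op.n_nodes:
        raise ValueError(
            f"operator over {op.n_nodes} cells cannot diffuse {x.shape[0]} rows"
        )
    if n_steps > OVERSMOOTHING_WARN_STEPS:
        logger.warning(
            "diffusing %d steps; repeated averaging collapses columns toward "
            "a constant profile (oversmoothing)",
            n_steps,
        )
    norms = []
    a = op.operator
    for _ in range(n_steps):
        new = a @ x
        norms.append(float(np.max(np.abs(new - x))) if x.size else 0.0)
        x = new
    return x, DiffusionDiagnostics(n_iter=n_steps, change_norms=norms)


def stationary_distribution(
    op: NormalizedAdjacency, tol: float = 1e-12, max_iter: int = 10_000
) -> np.ndarray:
    """Leading left eigenvector of a row-stochastic operator, by power iteration.

    Diagnostic only: π with π = Ãᵀπ, π ≥ 0, Σπ = 1.  This is the profile
    every column collapses to under unlimited diffusion.
    """
    if op.mode != RANDOM_WALK:
        raise ValueError("stationary distribution requires a row-stochastic operator")
    at = op.operator.T.tocsr()
    pi = np.full(op.n_nodes, 1.0 / op.n_nodes)
    for _ in range(max_iter):
        new = at @ pi
        s = new.sum()
        if s <= 0:
            raise ValueError("power iteration collapsed to zero mass")
        new = new / s
        if np.max(np.abs(new - pi)) < tol:
            pi = new
            break
        pi = new
    return pi


def run_scbfp(x, cfg: ScBFPConfig | None = None, **overrides):
    """Run the full warm-up + diffusion pipeline on a gene x cell matrix.

    Thin functional wrapper over :class:`scbfp.estimator.ScBFPImputer`;
    accepts a :class:`~scbfp.io.GeneCellMatrix` (any orientation) or a plain
    gene x cell array.  Returns ``(imputed, report)`` where ``imputed`` is a
    cell x gene :class:`~scbfp.io.GeneCellMatrix` (or ndarray for array
    input) and ``report`` is the run metadata dict.
    """
    from .estimator import ScBFPImputer
    from .io import GeneCellMatrix

    cfg = cfg or ScBFPConfig()
    if overrides:
        cfg = ScBFPConfig(**{**cfg.__dict__, **overrides})
    cfg.validate()
    est = ScBFPImputer.from_config(cfg)

    if isinstance(x, GeneCellMatrix):
        gc = x.as_gene_by_cell()
        imputed = est.fit_transform(gc.values.T if sp.issparse(gc.values) else gc.to_dense().T)
        out = GeneCellMatrix(imputed, gc.gene_ids, gc.cell_ids, "cell_by_gene")
        return out, est.report_
    imputed = est.fit_transform(np.asarray(x).T)
    return imputed, est.report_
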