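"""Clustered scRNA-seq-like count matrices with ground truth, plus masking.

The generator emulates the statistical structure an imputer relies on:
cells of the same type share a mean expression profile (so cell-cell cosine
neighborhoods are informative) and co-regulated genes share expression
patterns across cells (so gene-gene neighborhoods are informative).
Concretely, per-gene baseline means are log-normal, each cell type shifts a
random subset of genes up or down by a fixed log-fold change, cells carry
multiplicative log-normal size factors, counts are negative-binomial
(gamma-Poisson) around the resulting means, and an optional dropout process
zeroes observed counts either uniformly or preferentially at low-expression
entries.  The default dimensions follow the simulated benchmark regime of
3000 cells x 2000 genes with five cell types.

All randomness flows through one ``numpy.random.default_rng`` stream per
call, so a seed fully determines the output on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
import scipy.sparse as sp

from .io import GeneCellMatrix, LabelVector


@dataclass
class SyntheticSpec:
    """Parameters of the clustered count generator.

    ``dispersion`` is the negative-binomial size parameter theta
    (variance = mu + mu^2 / theta); large theta approaches Poisson.
    ``de_log_fold`` is a natural-log fold change applied to each type's
    differentially expressed genes.
    """

    n_cells: int = 3000
    n_genes: int = 2000
    n_types: int = 5
    type_proportions: List[float] | None = None
    de_fraction: float = 0.2
    de_log_fold: float = 1.0
    dispersion: float = 2.0
    size_factor_sd: float = 0.3
    dropout_rate: float = 0.0
    dropout_mode: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.type_proportions is None:
            self.type_proportions = [1.0 / self.n_types] * self.n_types
        self.validate()

    def validate(self) -> None:
        if self.n_types > self.n_cells:
            raise ValueError("more cell types than cells is infeasible")
        props = np.asarray(self.type_proportions, dtype=float)
        if props.shape != (self.n_types,) or not np.isclose(props.sum(), 1.0):
            raise ValueError("type_proportions must be a simplex vector of length n_types")
        if np.any(props <= 0):
            raise ValueError("every type needs positive prevalence")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.dropout_mode not in ("uniform", "intensity_dependent"):
            raise ValueError(f"unknown dropout_mode {self.dropout_mode!r}")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.size_factor_sd < 0:
            raise ValueError("size_factor_sd must be >= 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")


def rare_type_proportions(n_types: int, rare_prevalence: float = 0.02) -> list[float]:
    """One rare type at ``rare_prevalence``, the rest uniform (long-tail preset)."""
    if not 0 < rare_prevalence < 1.0 / n_types:
        raise ValueError("rare_prevalence must be below the uniform share")
    rest = (1.0 - rare_prevalence) / (n_types - 1)
    return [rest] * (n_types - 1) + [rare_prevalence]


@dataclass
class DropoutExperiment:
    """A masking experiment: original matrix, corrupted copy, masked coords."""

    original: GeneCellMatrix
    corrupted: GeneCellMatrix
    masked_coords: np.ndarray  # (n, 2) array of (gene, cell) indices
    masked_values: np.ndarray
    rate: float


def _calibrate_intensity_dropout(mu_nz: np.ndarray, rate: float) -> float:
    """Find lam with mean(exp(-lam * mu)) = rate over non-zero entries."""
    lo, hi = 0.0, 1.0
    while np.mean(np.exp(-hi * mu_nz)) > rate:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.mean(np.exp(-mid * mu_nz)) > rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_counts(
    spec: SyntheticSpec,
) -> tuple[GeneCellMatrix, LabelVector, np.ndarray]:
    """Draw a clustered count matrix with labels and the biological-zero mask.

    Returns ``(matrix, labels, true_zero_mask)``: the matrix is the
    post-dropout gene x cell count matrix, labels give each cell's true
    type, and ``true_zero_mask`` marks entries whose *pre-dropout* count was
    already zero (true biological zeros, as opposed to dropout zeros).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    G, C, T = spec.n_genes, spec.n_cells, spec.n_types

    # per-gene baseline mean on the log scale, shared by all types
    base_log_mean = rng.normal(loc=0.0, scale=1.0, size=G)

    # per-type DE shifts: each type up/down-regulates its own random gene set
    type_log_shift = np.zeros((G, T))
    n_de = int(round(spec.de_fraction * G))
    for t in range(T):
        de_genes = rng.choice(G, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        type_log_shift[de_genes, t] = signs * spec.de_log_fold

    # cell type assignment and multiplicative size factors (mean 1)
    types = rng.choice(T, size=C, p=np.asarray(spec.type_proportions))
    sf = rng.lognormal(
        mean=-0.5 * spec.size_factor_sd**2, sigma=spec.size_factor_sd, size=C
    )

    mu = np.exp(base_log_mean[:, None] + type_log_shift[:, types]) * sf[None, :]

    # gamma-Poisson mixture = negative binomial with size theta
    theta = spec.dispersion
    lam = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(lam).astype(float)
    true_zero_mask = counts == 0

    if spec.dropout_rate > 0:
        nz = counts > 0
        if spec.dropout_mode == "uniform":
            drop = rng.random(size=counts.shape) < spec.dropout_rate
        else:
            lam_d = _calibrate_intensity_dropout(mu[nz], spec.dropout_rate)
            drop = rng.random(size=counts.shape) < np.exp(-lam_d * mu)
        counts[nz & drop] = 0.0

    gene_ids = [f"gene_{i}" for i in range(G)]
    cell_ids = [f"cell_{j}" for j in range(C)]
    matrix = GeneCellMatrix(counts, gene_ids, cell_ids, "gene_by_cell")
    labels = LabelVector(cell_ids, [f"type_{t}" for t in types])
    return matrix, labels, true_zero_mask


def mask_nonzeros(m: GeneCellMatrix, rate: float, seed: int) -> DropoutExperiment:
    """Zero out a uniform sample of ``round(rate * n_nonzero)`` observed entries.

    This is the recovery benchmark's corruption step: masked coordinates and
    their original values are recorded so an imputer's output can be scored
    against ground truth at exactly those entries.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    g = m.as_gene_by_cell()
    dense = g.to_dense()
    nz_g, nz_c = np.nonzero(dense)
    n_nonzero = nz_g.size
    if n_nonzero == 0:
        raise ValueError("matrix has no non-zero entries to mask")
    n_mask = int(round(rate * n_nonzero))
    if rate > 0 and n_mask == 0:
        raise ValueError(f"rate={rate} leaves zero maskable entries")

    rng = np.random.default_rng(seed)
    picked = rng.choice(n_nonzero, size=n_mask, replace=False)
    coords = np.column_stack([nz_g[picked], nz_c[picked]])
    values = dense[coords[:, 0], coords[:, 1]].copy()

    corrupted = dense.copy()
    corrupted[coords[:, 0], coords[:, 1]] = 0.0
    return DropoutExperiment(
        original=g,
        corrupted=GeneCellMatrix(corrupted, g.gene_ids, g.cell_ids, "gene_by_cell"),
        masked_coords=coords,
        masked_values=values,
        rate=rate,
    )
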