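"""Reading, writing and light preprocessing of gene x cell expression matrices.

Supported formats:

* ``mtx_dir`` -- a 10x-style directory holding ``matrix.mtx[.gz]`` plus
  ``features.tsv[.gz]`` (or ``genes.tsv``) and ``barcodes.tsv[.gz]``; genes
  are rows by convention.
* ``csv`` -- dense CSV/TSV with a header row of cell identifiers and a first
  column of gene identifiers (genes are rows).
* ``h5`` -- an AnnData ``.h5ad`` container (cells are observations, i.e. the
  stored matrix is cell x gene and is transposed on load).

The in-memory canonical orientation is gene-by-cell; every public routine
records the orientation explicitly so downstream code can transpose safely.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

GENE_BY_CELL = "gene_by_cell"
CELL_BY_GENE = "cell_by_gene"


class FormatError(ValueError):
    """Raised when an on-disk matrix does not match the declared format."""


class ValidationError(ValueError):
    """Raised when matrix contents violate the non-negativity/shape contract."""


@dataclass
class GeneCellMatrix:
    """A non-negative expression matrix with gene and cell identifiers.

    ``values`` may be a dense ndarray or any scipy sparse matrix; axis order
    is given by ``orientation`` (``gene_by_cell`` means genes are rows).
    """

    values: "np.ndarray | sp.spmatrix"
    gene_ids: List[str]
    cell_ids: List[str]
    orientation: str = GENE_BY_CELL

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        self.validate()

    # -- basic geometry ---------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def shape(self):
        return self.values.shape

    def validate(self) -> None:
        if self.orientation not in (GENE_BY_CELL, CELL_BY_GENE):
            raise ValidationError(f"unknown orientation {self.orientation!r}")
        expect = (
            (self.n_genes, self.n_cells)
            if self.orientation == GENE_BY_CELL
            else (self.n_cells, self.n_genes)
        )
        if tuple(self.values.shape) != expect:
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells "
                f"({self.orientation})"
            )
        data = self.values.data if sp.issparse(self.values) else self.values
        data = np.asarray(data)
        if data.size and not np.all(np.isfinite(data)):
            raise ValidationError("matrix contains non-finite entries")
        if data.size and data.min() < 0:
            raise ValidationError("matrix contains negative entries")

    # -- transforms -------------------------------------------------------
    def transpose(self) -> "GeneCellMatrix":
        """Flip axis order; orientation metadata flips with it."""
        other = CELL_BY_GENE if self.orientation == GENE_BY_CELL else GENE_BY_CELL
        return GeneCellMatrix(self.values.T, self.gene_ids, self.cell_ids, other)

    def as_gene_by_cell(self) -> "GeneCellMatrix":
        return self if self.orientation == GENE_BY_CELL else self.transpose()

    def as_cell_by_gene(self) -> "GeneCellMatrix":
        return self if self.orientation == CELL_BY_GENE else self.transpose()

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def with_values(self, values) -> "GeneCellMatrix":
        return replace(self, values=values)


@dataclass
class LabelVector:
    """Per-cell categorical labels, aligned to cells by identifier."""

    cell_ids: List[str]
    labels: List

    def __post_init__(self) -> None:
        self.cell_ids = list(self.cell_ids)
        self.labels = list(self.labels)
        if len(self.cell_ids) != len(self.labels):
            raise ValidationError("one label per cell required")

    def aligned_to(self, m: GeneCellMatrix) -> np.ndarray:
        """Return labels reordered to match ``m.cell_ids``."""
        lut = dict(zip(self.cell_ids, self.labels))
        missing = [c for c in m.cell_ids if c not in lut]
        if missing:
            raise ValidationError(f"labels missing for cells: {missing[:5]}...")
        return np.asarray([lut[c] for c in m.cell_ids])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_one(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for cand in (directory / stem, directory / (stem + ".gz")):
            if cand.exists():
                return cand
    raise FormatError(f"none of {list(stems)} found in {directory}")


def _read_id_column(path: Path) -> List[str]:
    with _open_maybe_gz(path) as fh:
        out = []
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t")[0])
    return out


def read_count_matrix(path, format: str) -> GeneCellMatrix:
    """Load an expression matrix with identifiers attached.

    ``format`` is one of ``mtx_dir``, ``csv``, ``h5``.  Sparse storage is
    preserved for sparse inputs; the returned orientation is always
    gene-by-cell.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path} does not exist")

    if format == "mtx_dir":
        if not path.is_dir():
            raise FormatError(f"{path} is not a directory")
        mtx = _find_one(path, ["matrix.mtx"])
        genes_f = _find_one(path, ["features.tsv", "genes.tsv", "features.txt"])
        cells_f = _find_one(path, ["barcodes.tsv", "barcodes.txt"])
        try:
            values = mmread(str(mtx)).tocsr()
        except Exception as exc:  # noqa: BLE001 - wrap as format error
            raise FormatError(f"cannot parse {mtx}: {exc}") from exc
        gene_ids = _read_id_column(genes_f)
        cell_ids = _read_id_column(cells_f)
        if values.shape != (len(gene_ids), len(cell_ids)):
            raise ValidationError(
                f"matrix is {values.shape} but found {len(gene_ids)} features "
                f"and {len(cell_ids)} barcodes"
            )
        return GeneCellMatrix(values, gene_ids, cell_ids, GENE_BY_CELL)

    if format == "csv":
        if path.stat().st_size == 0:
            raise FormatError(f"{path} is empty")
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"cannot parse {path}: {exc}") from exc
        if df.shape[1] == 0:
            raise FormatError(f"{path} has no data columns")
        return GeneCellMatrix(
            df.to_numpy(dtype=float),
            [str(g) for g in df.index],
            [str(c) for c in df.columns],
            GENE_BY_CELL,
        )

    if format == "h5":
        import anndata as ad

        try:
            adata = ad.read_h5ad(path)
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"cannot parse {path} as h5ad: {exc}") from exc
        values = adata.X
        if sp.issparse(values):
            values = values.T.tocsr()
        else:
            values = np.asarray(values).T
        return GeneCellMatrix(
            values,
            [str(v) for v in adata.var_names],
            [str(o) for o in adata.obs_names],
            GENE_BY_CELL,
        )

    raise FormatError(f"unknown format {format!r}")


def write_matrix(
    m: GeneCellMatrix, path, format: str, orientation: str = GENE_BY_CELL
) -> None:
    """Write ``m`` so that :func:`read_count_matrix` round-trips it.

    ``orientation`` controls the on-disk axis order for csv/mtx (the reader
    assumes genes are rows, so only the default round-trips).
    """
    path = Path(path)
    g = m.as_gene_by_cell() if orientation == GENE_BY_CELL else m.as_cell_by_gene()
    if format == "csv" and orientation == CELL_BY_GENE:
        df = pd.DataFrame(g.to_dense(), index=g.cell_ids, columns=g.gene_ids)
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        df.to_csv(path, sep=sep)
        return
    g = g.as_gene_by_cell()

    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        values = g.values if sp.issparse(g.values) else sp.coo_matrix(g.values)
        mmwrite(str(path / "matrix.mtx"), values)
        (path / "features.tsv").write_text("".join(f"{x}\n" for x in g.gene_ids))
        (path / "barcodes.tsv").write_text("".join(f"{x}\n" for x in g.cell_ids))
        return

    if format == "csv":
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        df = pd.DataFrame(g.to_dense(), index=g.gene_ids, columns=g.cell_ids)
        df.to_csv(path, sep=sep)
        return

    if format == "h5":
        import anndata as ad

        c = m.as_cell_by_gene()
        X = c.values if sp.issparse(c.values) else np.asarray(c.values)
        adata = ad.AnnData(
            X=X.tocsr() if sp.issparse(X) else X,
            obs=pd.DataFrame(index=pd.Index(c.cell_ids, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(c.gene_ids, name="gene_id")),
        )
        adata.write_h5ad(path)
        return

    raise FormatError(f"unknown format {format!r}")


def read_labels(path) -> LabelVector:
    """Read a two-column CSV (cell_id, label)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (cell_id, label)")
    return LabelVector(
        [str(c) for c in df.iloc[:, 0]], [str(v) for v in df.iloc[:, 1]]
    )


def write_labels(lv: LabelVector, path) -> None:
    pd.DataFrame({"cell_id": lv.cell_ids, "label": lv.labels}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    m: GeneCellMatrix,
    normalize: bool = True,
    log1p: bool = True,
    target_sum: float | None = None,
) -> GeneCellMatrix:
    """Library-size normalization and log transform.

    Each cell's total count is scaled to ``target_sum`` (median cell total by
    default), then ``log(1+x)`` is applied entry-wise.  Both transforms fix
    zero entries, so the observed/zero partition is unchanged.  Cells with a
    zero total are left unscaled with a warning.
    """
    g = m.as_gene_by_cell()
    values = g.values.astype(float)

    if normalize:
        totals = np.asarray(values.sum(axis=0)).ravel()
        if target_sum is None:
            positive = totals[totals > 0]
            target_sum = float(np.median(positive)) if positive.size else 1.0
        if target_sum <= 0:
            raise ValidationError("target_sum must be positive")
        factors = np.ones_like(totals)
        nz = totals > 0
        factors[nz] = target_sum / totals[nz]
        if not np.all(nz):
            warnings.warn(
                f"{int((~nz).sum())} cell(s) have zero total count; left unscaled",
                RuntimeWarning,
                stacklevel=2,
            )
        if sp.issparse(values):
            values = values @ sp.diags(factors)
        else:
            values = values * factors[np.newaxis, :]

    if log1p:
        if sp.issparse(values):
            values = values.copy()
            values.data = np.log1p(values.data)
        else:
            values = np.log1p(values)

    return GeneCellMatrix(values, g.gene_ids, g.cell_ids, GENE_BY_CELL)
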