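"""Recovery-error and clustering metrics for imputation benchmarks.

Two views of imputation quality: how well artificially masked counts are
recovered (median L1 and RMSE at the masked coordinates only), and how much
downstream cell clustering improves (ARI, NMI, clustering accuracy under
the optimal cluster-to-class assignment, and macro-F1 under that same
assignment, which is the metric sensitive to rare cell types).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import (
    adjusted_rand_score,
    confusion_matrix,
    normalized_mutual_info_score,
)

from .io import GeneCellMatrix, LabelVector
from .synthetic import DropoutExperiment


@dataclass
class RecoveryScores:
    median_l1: float
    rmse: float
    n_masked: int


@dataclass
class ClusteringScores:
    ari: float
    nmi: float
    ca: float
    macro_f1: float


def recovery_error(exp: DropoutExperiment, imputed) -> RecoveryScores:
    """Median |imputed − original| and RMSE over the masked coordinates only.

    ``imputed`` may be a :class:`GeneCellMatrix` in either orientation or a
    plain gene x cell array aligned with ``exp.original``.
    """
    if exp.masked_coords.shape[0] == 0:
        raise ValueError("experiment has an empty mask; nothing to score")
    if isinstance(imputed, GeneCellMatrix):
        arr = imputed.as_gene_by_cell().to_dense()
    else:
        arr = np.asarray(imputed, dtype=float)
    orig = exp.original.as_gene_by_cell()
    if arr.shape != orig.shape:
        raise ValueError(
            f"imputed shape {arr.shape} does not match original {orig.shape}"
        )
    g, c = exp.masked_coords[:, 0], exp.masked_coords[:, 1]
    diff = arr[g, c] - exp.masked_values
    return RecoveryScores(
        median_l1=float(np.median(np.abs(diff))),
        rmse=float(np.sqrt(np.mean(diff**2))),
        n_masked=int(diff.size),
    )


def _aligned_codes(pred: LabelVector, truth: LabelVector):
    if len(pred.labels) != len(truth.labels):
        raise ValueError("label vectors have different lengths")
    order = {c: i for i, c in enumerate(truth.cell_ids)}
    if set(pred.cell_ids) != set(truth.cell_ids):
        raise ValueError("cell identifiers do not match between label vectors")
    pred_sorted = [None] * len(truth.cell_ids)
    for cid, lab in zip(pred.cell_ids, pred.labels):
        pred_sorted[order[cid]] = lab
    t_codes, _ = _codes(truth.labels)
    p_codes, _ = _codes(pred_sorted)
    return p_codes, t_codes


def _codes(labels):
    uniq = sorted(set(labels), key=str)
    lut = {u: i for i, u in enumerate(uniq)}
    return np.asarray([lut[x] for x in labels]), uniq


def clustering_scores(pred: LabelVector, truth: LabelVector) -> ClusteringScores:
    """ARI, NMI, clustering accuracy and macro-F1 against gold labels.

    CA maximizes the matched fraction over one-to-one cluster-to-class
    assignments (Hungarian algorithm on the confusion matrix, zero-padded
    when rectangular); macro-F1 is computed under that same assignment, so
    predicted clusters left unmatched count entirely as errors.
    """
    p, t = _aligned_codes(pred, truth)
    ari = float(adjusted_rand_score(t, p))
    nmi = float(normalized_mutual_info_score(t, p))

    n_t, n_p = int(t.max()) + 1, int(p.max()) + 1
    side = max(n_t, n_p)
    conf = confusion_matrix(t, p, labels=np.arange(side)).astype(float)
    rows, cols = linear_sum_assignment(conf, maximize=True)
    ca = float(conf[rows, cols].sum() / len(t))

    # macro-F1 over true classes, predicted cluster c mapped to class rows[c]
    cluster_to_class = {c: r for r, c in zip(rows, cols)}
    mapped = np.asarray([cluster_to_class.get(c, -1) for c in p])
    f1s = []
    for cls in range(n_t):
        tp = np.sum((mapped == cls) & (t == cls))
        fp = np.sum((mapped == cls) & (t != cls))
        fn = np.sum((mapped != cls) & (t == cls))
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else 0.0)
    return ClusteringScores(ari=ari, nmi=nmi, ca=ca, macro_f1=float(np.mean(f1s)))


def cluster_cells(
    m: GeneCellMatrix,
    n_clusters: int,
    seed: int = 0,
    use_pca: bool = True,
    n_components: int = 50,
) -> LabelVector:
    """k-means on log1p expression (optionally PCA-reduced), fixed seed.

    A deterministic default clustering for benchmarking imputation output;
    10 k-means restarts, all seeded.
    """
    c = m.as_cell_by_gene()
    if n_clusters < 1 or n_clusters > c.n_cells:
        raise ValueError("n_clusters must be in [1, n_cells]")
    x = np.log1p(c.to_dense())
    if use_pca:
        k = min(n_components, x.shape[0] - 1, x.shape[1])
        if k >= 1 and k < min(x.shape):
            x = PCA(n_components=k, random_state=seed).fit_transform(x)
    if n_clusters == c.n_cells:
        labels = np.arange(c.n_cells)
    else:
        labels = KMeans(
            n_clusters=n_clusters, n_init=10, random_state=seed
        ).fit_predict(x)
    return LabelVector(c.cell_ids, [f"cluster_{int(v)}" for v in labels])


def knn_label_purity(graph_adjacency, labels: np.ndarray) -> float:
    """Mean fraction of each node's graph neighbors sharing its label.

    Measures how well a cell-cell graph respects cell-type structure; used
    to verify that the graph rebuilt from the warmed-up matrix is cleaner
    than the one built from the corrupted raw matrix.
    """
    labels = np.asarray(labels)
    adj = graph_adjacency.tocsr()
    fracs = []
    for i in range(adj.shape[0]):
        nbrs = adj.indices[adj.indptr[i] : adj.indptr[i + 1]]
        if nbrs.size:
            fracs.append(np.mean(labels[nbrs] == labels[i]))
    return float(np.mean(fracs))


def scores_to_json(path, **score_objects) -> None:
    """Serialize score dataclasses to a JSON file."""
    with open(path, "w") as fh:
        json.dump({k: asdict(v) for k, v in score_objects.items()}, fh, indent=2)


def scores_to_tsv_row(path, header: bool = True, **fields) -> None:
    """Append a one-row TSV of flat score fields for cross-run aggregation."""
    keys = list(fields)
    with open(path, "a") as fh:
        if header:
            fh.write("\t".join(keys) + "\n")
        fh.write("\t".join(str(fields[k]) for k in keys) + "\n")
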