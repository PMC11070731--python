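import numpy as np
import pytest

from scbfp import (
    ScBFPConfig,
    SyntheticSpec,
    cosine_knn,
    connectivity_report,
    generate_counts,
    mask_nonzeros,
    normalize,
    rare_type_proportions,
    run_scbfp,
)
from scbfp.io import preprocess


def random_connected_operator(rng, n, k=3, mode="symmetric", self_loops=True):
    """A normalized kNN operator on random points, guaranteed connected."""
    for _ in range(50):
        g = cosine_knn(rng.normal(size=(n, 5)), k)
        if connectivity_report(g)[1]:
            return g, normalize(g, mode, add_self_loops=self_loops)
        k += 1
    raise RuntimeError("could not build a connected graph")


@pytest.fixture(scope="session")
def benchmark_fixture():
    """The recovery-benchmark study conditions, shared across tests.

    500 cells x 300 genes, four types with one rare type at 2% prevalence,
    log-fold 1.5 differential expression; expression is library-normalized
    and log1p-transformed, then 40% of non-zeros are masked (seed 0) and
    imputed with default settings.
    """
    spec = SyntheticSpec(
        n_cells=500,
        n_genes=300,
        n_types=4,
        type_proportions=rare_type_proportions(4, 0.02),
        de_log_fold=1.5,
        dropout_rate=0.0,
        seed=0,
    )
    counts, labels, true_zero_mask = generate_counts(spec)
    expr = preprocess(counts)
    exp = mask_nonzeros(expr, rate=0.4, seed=0)
    imputed, report = run_scbfp(exp.corrupted, ScBFPConfig())
    return {
        "spec": spec,
        "counts": counts,
        "expr": expr,
        "labels": labels,
        "true_zero_mask": true_zero_mask,
        "experiment": exp,
        "imputed": imputed,
        "report": report,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
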