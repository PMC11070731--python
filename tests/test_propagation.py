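import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from scbfp.graph import KNNGraph, normalize
from scbfp.propagation import (
    ObservedMask,
    SingularComponentError,
    closed_form_impute,
    closed_form_impute_matrix,
    dirichlet_energy,
    propagate_batched,
    propagate_clamped,
)
from tests.conftest import random_connected_operator


def graph_from_edges(n, edges):
    a = sp.lil_matrix((n, n))
    for i, j in edges:
        a[i, j] = a[j, i] = 1.0
    return KNNGraph(a.tocsr(), k=1)


def random_masked_problem(seed, n=30, n_cols=3):
    """Connected operator + matrix with >=1 observed node per column."""
    rng = np.random.default_rng(seed)
    _, op = random_connected_operator(rng, n, mode="symmetric")
    x = rng.gamma(2.0, 1.0, size=(n, n_cols))
    x[rng.random(size=x.shape) < 0.6] = 0.0
    for c in range(n_cols):
        if not (x[:, c] > 0).any():
            x[rng.integers(n), c] = 1.0
    return x, op, ObservedMask.from_matrix(x)


class TestPropagateClamped:
    def test_no_zeros_is_identity(self, rng):
        _, op = random_connected_operator(rng, 10, mode="symmetric")
        x = rng.gamma(2.0, 1.0, size=(10, 4)) + 0.1
        mask = ObservedMask.from_matrix(x)
        out, n_iter, res = propagate_clamped(x, op, mask, max_iter=20)
        np.testing.assert_array_equal(out, x)
        assert res == 0.0

    def test_single_edge_zero_converges_to_observed_value(self):
        # with self-loops the zero entry follows the geometric series
        # v * sum (1/2)^j -> v; without, one step lands exactly on v
        g = graph_from_edges(2, [(0, 1)])
        x = np.array([[3.0], [0.0]])
        mask = ObservedMask.from_matrix(x)
        op_plain = normalize(g, "symmetric", add_self_loops=False)
        out, n_iter, _ = propagate_clamped(x, op_plain, mask, max_iter=5)
        assert out[1, 0] == pytest.approx(3.0)
        op_loops = normalize(g, "symmetric", add_self_loops=True)
        out, _, _ = propagate_clamped(x, op_loops, mask, max_iter=200, tol=1e-12)
        assert out[1, 0] == pytest.approx(3.0, abs=1e-9)

    def test_star_center_reaches_harmonic_value(self):
        # leaves observed at 1 and 3; the center's fixed point is
        # (1+3)/sqrt(2) = 2*sqrt(2) under symmetric normalization
        g = graph_from_edges(3, [(0, 1), (0, 2)])
        op = normalize(g, "symmetric", add_self_loops=False)
        x = np.array([[0.0], [1.0], [3.0]])
        mask = ObservedMask.from_matrix(x)
        out, _, _ = propagate_clamped(x, op, mask, max_iter=5)
        assert out[0, 0] == pytest.approx(2 * np.sqrt(2))

    def test_observed_entries_bit_identical(self, rng):
        x, op, mask = random_masked_problem(1)
        out, _, _ = propagate_clamped(x, op, mask, max_iter=60)
        assert np.array_equal(out[mask.mask], x[mask.mask])

    def test_output_non_negative(self, rng):
        x, op, mask = random_masked_problem(2)
        out, _, _ = propagate_clamped(x, op, mask, max_iter=60)
        assert out.min() >= 0

    def test_imputed_values_bounded_by_amplified_observed_max(self):
        for seed in range(5):
            x, op, mask = random_masked_problem(seed, n=25, n_cols=2)
            out, _, _ = propagate_clamped(x, op, mask, max_iter=200, tol=1e-12)
            deg = np.asarray((op.operator != 0).sum(axis=1)).ravel().astype(float)
            rho = np.sqrt(deg.max() / deg.min())
            for c in range(x.shape[1]):
                assert out[:, c].max() <= x[:, c].max() * rho + 1e-9

    def test_residual_tail_decreases(self):
        x, op, mask = random_masked_problem(3, n=40, n_cols=1)
        _, _, r10 = propagate_clamped(x, op, mask, max_iter=10, tol=0.0)
        _, _, r20 = propagate_clamped(x, op, mask, max_iter=20, tol=0.0)
        _, _, r40 = propagate_clamped(x, op, mask, max_iter=40, tol=0.0)
        assert r20 < r10
        assert r40 < r20

    def test_generalized_step_size_converges_to_same_fixed_point(self):
        x, op, mask = random_masked_problem(4, n=20, n_cols=1)
        full, _, _ = propagate_clamped(x, op, mask, max_iter=3000, tol=1e-12)
        half, _, _ = propagate_clamped(x, op, mask, max_iter=6000, tol=1e-12, h=0.5)
        np.testing.assert_allclose(half, full, atol=1e-8)

    def test_shape_mismatch_and_nonfinite_rejected(self, rng):
        x, op, mask = random_masked_problem(5)
        with pytest.raises(ValueError):
            propagate_clamped(x[:-1], op, ObservedMask(mask.mask[:-1]), 10)
        bad = x.copy()
        bad[0, 0] = np.nan
        # mask marks nan position as observed=False is irrelevant; input check fires
        with pytest.raises(ValueError):
            propagate_clamped(bad, op, mask, 10)

    def test_unreachable_column_stays_zero(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        op = normalize(g, "symmetric", add_self_loops=True)
        x = np.array([[2.0], [0.0], [0.0], [0.0]])
        out, _, _ = propagate_clamped(x, op, ObservedMask.from_matrix(x), 100)
        assert out[2, 0] == 0.0 and out[3, 0] == 0.0
        assert out[1, 0] > 0


class TestClosedForm:
    def test_empty_zero_set_returns_empty(self, rng):
        _, op = random_connected_operator(rng, 8, mode="symmetric")
        x = np.ones(8)
        assert closed_form_impute(x, op, np.ones(8, bool)).size == 0

    def test_star_solve_matches_hand_value(self):
        g = graph_from_edges(3, [(0, 1), (0, 2)])
        op = normalize(g, "symmetric", add_self_loops=False)
        x = np.array([0.0, 1.0, 3.0])
        out = closed_form_impute(x, op, x > 0)
        np.testing.assert_allclose(out, [2 * np.sqrt(2)])

    def test_iterative_path_matches_oracle(self):
        x, op, mask = random_masked_problem(6, n=30, n_cols=3)
        iterated, _, _ = propagate_clamped(x, op, mask, max_iter=5000, tol=1e-10)
        oracle = closed_form_impute_matrix(x, op, mask)
        np.testing.assert_allclose(iterated, oracle, atol=1e-8)

    def test_component_without_observed_node_errors(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        op = normalize(g, "symmetric", add_self_loops=True)
        x = np.array([2.0, 0.0, 0.0, 0.0])
        with pytest.raises(SingularComponentError):
            closed_form_impute(x, op, x > 0)


class TestDirichletEnergy:
    def test_constant_column_on_regular_graph_has_zero_energy(self):
        # 4-cycle with self-loops is 3-regular: constant vectors are in the
        # nullspace of the symmetric Laplacian
        g = graph_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        op = normalize(g, "symmetric", add_self_loops=True)
        x = np.full((4, 2), 2.5)
        assert dirichlet_energy(x, op) == pytest.approx(0.0, abs=1e-12)

    def test_hand_expanded_quadratic_form(self):
        g = graph_from_edges(2, [(0, 1)])
        op = normalize(g, "symmetric", add_self_loops=False)
        assert dirichlet_energy(np.array([1.0, 0.0]), op) == pytest.approx(0.5)

    def test_converged_energy_matches_oracle_energy(self):
        x, op, mask = random_masked_problem(7, n=25, n_cols=2)
        iterated, _, _ = propagate_clamped(x, op, mask, max_iter=5000, tol=1e-10)
        oracle = closed_form_impute_matrix(x, op, mask)
        assert dirichlet_energy(iterated, op) == pytest.approx(
            dirichlet_energy(oracle, op), abs=1e-8
        )

    def test_propagation_decreases_energy_of_zero_initialization(self):
        x, op, mask = random_masked_problem(8, n=30, n_cols=1)
        warmed, _, _ = propagate_clamped(x, op, mask, max_iter=2000, tol=1e-10)
        assert dirichlet_energy(warmed, op) <= dirichlet_energy(x, op) + 1e-10


class TestBatched:
    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.integers(min_value=1, max_value=9))
    def test_batched_equals_unbatched_exactly(self, batch_size):
        x, op, mask = random_masked_problem(9, n=20, n_cols=7)
        full, it_f, res_f = propagate_clamped(x, op, mask, max_iter=50)
        batched, it_b, res_b = propagate_batched(
            x, op, mask, max_iter=50, batch_size=batch_size
        )
        np.testing.assert_array_equal(batched, full)
        assert it_b == it_f
        assert res_b == pytest.approx(res_f)

    def test_sparse_input_batched_equals_dense_unbatched(self):
        x, op, mask = random_masked_problem(10, n=20, n_cols=5)
        full, _, _ = propagate_clamped(x, op, mask, max_iter=30)
        batched, _, _ = propagate_batched(
            sp.csr_matrix(x), op, mask, max_iter=30, batch_size=2
        )
        np.testing.assert_array_equal(batched, full)

    def test_oversized_batch_is_one_batch(self):
        x, op, mask = random_masked_problem(11, n=15, n_cols=3)
        a, _, _ = propagate_batched(x, op, mask, 20, batch_size=1000)
        b, _, _ = propagate_clamped(x, op, mask, 20)
        np.testing.assert_array_equal(a, b)
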