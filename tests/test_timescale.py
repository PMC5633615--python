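"""Slow/fast transform, singular perturbation blocks, reduced models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netaggr import (
    AreaPartition,
    ConnectivityNetwork,
    aggregate_system,
    build_transform,
    check_aggregability,
    orthonormal_difference_matrix,
    singular_perturbed_system,
    slow_fast_subsystems,
    split_connection_matrix,
)
from netaggr.synthgen import GeneratorConfig, generate_clustered_network
from netaggr.timescale import fast_initial_condition, sort_spectrum


class TestDifferenceMatrix:
    def test_two_node_row(self):
        Q = orthonormal_difference_matrix(2)
        np.testing.assert_allclose(
            Q, [[-1 / np.sqrt(2), 1 / np.sqrt(2)]], atol=1e-15
        )

    @settings(max_examples=19, deadline=None, derandomize=True)
    @given(n=st.integers(2, 20))
    def test_orthonormal_rows_with_ones_null_vector(self, n):
        Q = orthonormal_difference_matrix(n)
        assert Q.shape == (n - 1, n)
        np.testing.assert_allclose(Q @ Q.T, np.eye(n - 1), atol=1e-12)
        np.testing.assert_allclose(Q @ np.ones(n), 0.0, atol=1e-12)

    def test_rejects_singletons(self):
        with pytest.raises(ValueError):
            orthonormal_difference_matrix(1)


class TestTransform:
    def test_worked_example_shapes(self, ex1):
        tr = build_transform(ex1.partition)
        assert tr.U.shape == (8, 2)
        np.testing.assert_array_equal(np.diag(tr.Ma), [4.0, 4.0])
        assert tr.Q.shape == (6, 8)
        # Q is block diagonal over the two areas
        np.testing.assert_array_equal(tr.Q[:3, 4:], np.zeros((3, 4)))
        np.testing.assert_array_equal(tr.Q[3:, :4], np.zeros((3, 4)))
        np.testing.assert_allclose(
            tr.R, [[-1 / np.sqrt(2), 1 / np.sqrt(2)]], atol=1e-15
        )

    @pytest.mark.parametrize("sizes", [(2, 2), (4, 4), (3, 5, 2), (1, 4)])
    def test_invertibility_identity(self, sizes):
        # U G + Q^T Q = I: the slow/fast map is invertible with
        # inverse [U | Q^T]
        tr = build_transform(AreaPartition.from_sizes(sizes))
        N = sum(sizes)
        np.testing.assert_allclose(
            tr.U @ tr.G + tr.Q.T @ tr.Q, np.eye(N), atol=1e-12
        )

    def test_round_trip_map(self, ex1, rng):
        tr = build_transform(ex1.partition)
        x = rng.standard_normal(8)
        y, z = tr.to_slow_fast(x)
        np.testing.assert_allclose(tr.from_slow_fast(y, z), x, atol=1e-12)

    def test_single_area_has_no_interarea_matrix(self):
        tr = build_transform(AreaPartition.from_sizes((4,)))
        assert tr.R is None and tr.C is None


class TestSingularPerturbedSystem:
    def test_worked_example_slow_block(self, ex1):
        system = singular_perturbed_system(ex1)
        assert (system.cI, system.d, system.delta) == (2, 0.5, 0.25)
        np.testing.assert_allclose(system.A11, [[-1, 1], [1, -1]], atol=1e-12)
        eigs = sort_spectrum(np.linalg.eigvals(system.A11))
        np.testing.assert_allclose(eigs.real, [0.0, -2.0], atol=1e-12)

    def test_rescaling_is_exact(self, ex1):
        s = singular_perturbed_system(ex1)
        np.testing.assert_array_equal(s.A11, s.A11t / (s.cI * s.delta))
        np.testing.assert_array_equal(s.A12, s.A12t / (s.cI * s.delta))
        np.testing.assert_array_equal(s.A21, s.A21t / (s.cI * s.d))
        np.testing.assert_array_equal(s.A22, s.A22t / s.cI)

    def test_blocks_match_dense_product_oracle(self):
        net = generate_clustered_network(GeneratorConfig(sizes=(4, 5), seed=3))
        s = singular_perturbed_system(net)
        K_int, K_ext = split_connection_matrix(net)
        tr = build_transform(net.partition)
        np.testing.assert_allclose(
            s.A22t, tr.Q @ (K_int + K_ext) @ tr.Q.T, atol=1e-12
        )
        np.testing.assert_allclose(s.A11t, tr.G @ K_ext @ tr.U, atol=1e-12)
        np.testing.assert_allclose(s.A21t, tr.Q @ K_ext @ tr.U, atol=1e-12)

    def test_no_external_coupling_zeroes_coupling_blocks(self):
        net = generate_clustered_network(
            GeneratorConfig(sizes=(3, 3), external_per_area_max=0,
                            external_total=0, seed=0)
        )
        s = singular_perturbed_system(net, cI=2, d=0.5, delta=0.25)
        np.testing.assert_array_equal(s.A11t, np.zeros((2, 2)))
        np.testing.assert_array_equal(s.A12t, np.zeros((2, 4)))
        np.testing.assert_array_equal(s.A21t, np.zeros((4, 2)))
        # and the reduced slow matrix vanishes: no inter-area dynamics
        np.testing.assert_allclose(
            slow_fast_subsystems(s).A0, np.zeros((2, 2)), atol=1e-12
        )

    def test_zero_parameters_rejected(self, ex1):
        with pytest.raises(ValueError, match="positive"):
            singular_perturbed_system(ex1, d=0.0)

    def test_pseudoinverse_dialect_preserves_slow_spectrum(self, ex1):
        ortho = slow_fast_subsystems(singular_perturbed_system(ex1))
        plain = slow_fast_subsystems(
            singular_perturbed_system(ex1, q_dialect="difference")
        )
        np.testing.assert_allclose(
            np.sort(ortho.slow_eigs.real),
            np.sort(plain.slow_eigs.real),
            atol=1e-9,
        )


class TestReducedModels:
    def test_worked_example_slow_matrix(self, ex1):
        red = slow_fast_subsystems(singular_perturbed_system(ex1))
        assert red.aggregable
        np.testing.assert_allclose(
            red.A0,
            [[-0.7634, 0.7634], [0.7634, -0.7634]],
            atol=5e-5,
        )
        np.testing.assert_allclose(
            np.sort(red.slow_eigs.real), [-1.5267, 0.0], atol=1e-3
        )
        assert np.abs(red.slow_eigs.imag).max() < 1e-12

    def test_fast_block_is_hurwitz(self, ex1):
        red = slow_fast_subsystems(singular_perturbed_system(ex1))
        assert red.fast_eigs.real.max() < 0

    def test_fast_initial_condition_correction(self, ex1, rng):
        s = singular_perturbed_system(ex1)
        x0 = rng.standard_normal(8)
        _, z0 = s.transform.to_slow_fast(x0)
        y0 = s.transform.G @ x0
        expected = z0 + s.d * np.linalg.solve(s.A22, s.A21 @ y0)
        np.testing.assert_allclose(
            fast_initial_condition(s, x0), expected, atol=1e-12
        )

    def test_worked_example_aggregate(self, ex1):
        Ma, Ka, eigs = aggregate_system(ex1)
        np.testing.assert_array_equal(Ka, [[-2.0, 2.0], [2.0, -2.0]])
        np.testing.assert_allclose(
            np.sort(eigs.real), [-1.0, 0.0], atol=1e-12
        )

    def test_aggregate_without_external_links_is_zero(self):
        net = generate_clustered_network(
            GeneratorConfig(sizes=(3, 3), external_per_area_max=0,
                            external_total=0, seed=0)
        )
        _, Ka, _ = aggregate_system(net)
        np.testing.assert_array_equal(Ka, np.zeros((2, 2)))


def scaled_external(net, eps):
    """Network with external weights scaled by eps (same topology)."""
    K_int, K_ext = split_connection_matrix(net)
    return ConnectivityNetwork(K=K_int + eps * K_ext, partition=net.partition)


class TestSpectralConsistency:
    EPS = (1.0, 0.5, 0.25, 0.125)

    def test_slow_eigs_converge_to_reduced_spectrum(self, ex1):
        # the r smallest-magnitude eigenvalues of the full system (in
        # slow time units) approach the spectrum of A0 as the external
        # coupling is scaled down
        errors = []
        for eps in self.EPS:
            net = scaled_external(ex1, eps)
            s = singular_perturbed_system(net)
            red = slow_fast_subsystems(s)
            full = np.linalg.eigvals(net.K)
            slow = full[np.argsort(np.abs(full))[:2]] / (s.cI * s.delta)
            errors.append(
                np.abs(
                    np.sort(slow.real) - np.sort(red.slow_eigs.real)
                ).max()
            )
        assert all(a > b for a, b in zip(errors, errors[1:]))
        assert errors[-1] < errors[0] / 20

    def test_aggregate_matches_reduced_in_weak_coupling_limit(self, ex1):
        # eigenvalues of Ma^{-1} Ka and of A0 (both normalised per unit
        # of external weight) agree as the coupling vanishes
        errors = []
        for eps in self.EPS:
            net = scaled_external(ex1, eps)
            s = singular_perturbed_system(net)
            red = slow_fast_subsystems(s)
            a0_realtime = s.cI * s.delta * red.slow_eigs.real
            errors.append(
                np.abs(
                    np.sort(a0_realtime / eps)
                    - np.sort(red.aggregate_eigs.real / eps)
                ).max()
            )
        assert all(a > b for a, b in zip(errors, errors[1:]))

    def test_zero_is_always_a_slow_eigenvalue(self, clustered_net):
        red = slow_fast_subsystems(singular_perturbed_system(clustered_net))
        for eigs in (
            red.slow_eigs,
            red.aggregate_eigs,
            np.linalg.eigvals(clustered_net.K),
        ):
            assert np.abs(eigs).min() < 1e-9


class TestAggregability:
    def test_worked_example_is_aggregable(self, ex1):
        report = check_aggregability(ex1)
        assert report.aggregable
        assert report.reasons == ()
        assert (report.d, report.delta) == (0.5, 0.25)

    def test_forced_partition_without_internal_links(self):
        # a single 4-clique split into two areas of two non-adjacent
        # nodes each: area-2 nodes have no internal links
        K = np.array(
            [
                [-2.0, 0.0, 1.0, 1.0],
                [0.0, -2.0, 1.0, 1.0],
                [1.0, 1.0, -2.0, 0.0],
                [1.0, 1.0, 0.0, -2.0],
            ]
        )
        report = check_aggregability(
            ConnectivityNetwork(K=K, partition=AreaPartition((1, 1, 2, 2)))
        )
        assert not report.aggregable
        assert any("zero internal links" in r for r in report.reasons)

    def test_disconnected_area_interior_is_singular(self):
        # area 2's internal graph is two disjoint links, so the fast
        # block has a zero eigenvalue
        adjacency = np.zeros((6, 6))
        for i, j in [(0, 1), (2, 3), (4, 5)]:
            adjacency[i, j] = adjacency[j, i] = 1.0
        K = adjacency - np.diag(adjacency.sum(axis=1))
        report = check_aggregability(
            ConnectivityNetwork(K=K, partition=AreaPartition((1, 1, 2, 2, 2, 2)))
        )
        assert not report.aggregable
        assert "fast subsystem singular" in report.reasons
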