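"""Simulator unit and property tests: topology, weights, genotypes,
eQTL map and the SEM identity."""

import numpy as np
import pytest

from diffsem.simulate import (
    GRNAdjacency,
    GRNWeights,
    build_eqtl_effects,
    derive_condition2_weights,
    generate_adjacency,
    perturb_adjacency,
    simulate_expression,
    simulate_genotypes,
    simulate_paired_dataset,
    weights_from_adjacency,
    _perturbation_size,
)


class TestGenerateAdjacency:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_dag_edge_count_and_acyclicity(self, seed):
        rng = np.random.default_rng(seed)
        adj = generate_adjacency(30, 1, "dag", rng)
        assert adj.n_edges == 30
        assert adj.is_acyclic()
        assert np.all(np.diag(adj.entries) == 0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_dcg_contains_cycle(self, seed):
        rng = np.random.default_rng(seed)
        adj = generate_adjacency(10, 3, "dcg", rng)
        assert adj.n_edges == 30
        assert not adj.is_acyclic()
        assert np.all(np.diag(adj.entries) == 0)

    def test_two_gene_dag_caps_at_single_edge(self):
        # only one strict-triangle cell exists for p=2
        adj = generate_adjacency(2, 1, "dag", np.random.default_rng(0))
        assert adj.n_edges == 1

    def test_infeasible_edge_count_rejected(self):
        with pytest.raises(ValueError):
            generate_adjacency(3, 4, "dcg", np.random.default_rng(0))

    def test_bad_kind_rejected(self):
        with pytest.raises(ValueError):
            generate_adjacency(5, 1, "tree", np.random.default_rng(0))


class TestPerturbAdjacency:
    def test_rounding_rule(self):
        # 10% of 20 edges -> 2 flips; 10% of 30 -> nearest even of 3
        assert _perturbation_size(20, 0.1) == 2
        assert _perturbation_size(30, 0.1) in (2, 4)
        assert _perturbation_size(5, 0.1) == 2  # floor of 2
        assert _perturbation_size(100, 0.0) == 0

    @pytest.mark.parametrize("seed", range(20))
    @pytest.mark.parametrize("kind,n_e", [("dag", 2), ("dcg", 2)])
    def test_edge_count_conserved_and_flips_balanced(self, seed, kind, n_e):
        rng = np.random.default_rng(seed)
        A1 = generate_adjacency(12, n_e, kind, rng)
        A2, removed, added = perturb_adjacency(A1, 0.1, rng)
        assert A2.n_edges == A1.n_edges
        diff = A2.entries.astype(int) - A1.entries.astype(int)
        assert (diff == -1).sum() == len(removed)
        assert (diff == 1).sum() == len(added)
        assert len(removed) == len(added)
        if kind == "dag":
            assert A2.is_acyclic()

    def test_zero_fraction_is_identity(self):
        rng = np.random.default_rng(3)
        A1 = generate_adjacency(8, 1, "dag", rng)
        A2, removed, added = perturb_adjacency(A1, 0.0, rng)
        assert np.array_equal(A1.entries, A2.entries)
        assert removed == [] and added == []

    def test_exact_cell_difference_count(self):
        rng = np.random.default_rng(4)
        A1 = generate_adjacency(20, 1, "dag", rng)  # 20 edges
        A2, _, _ = perturb_adjacency(A1, 0.1, rng)
        assert (A1.entries != A2.entries).sum() == 2


class TestWeights:
    def test_support_and_magnitude(self, rng):
        A = generate_adjacency(10, 2, "dag", rng)
        B = weights_from_adjacency(A, rng)
        nz = B.entries[A.entries == 1]
        assert np.all((np.abs(nz) > 0.5) & (np.abs(nz) < 1.0))
        assert np.all(B.entries[A.entries == 0] == 0)

    def test_all_zero_adjacency_gives_zero_weights(self, rng):
        A = GRNAdjacency(np.zeros((4, 4), dtype=np.int8), "dag")
        B = weights_from_adjacency(A, rng)
        assert np.all(B.entries == 0)

    def test_moments_match_uniform_mixture(self):
        # |w| ~ U(0.5, 1) with random sign: E|w| = 0.75, P(w<0) = 0.5
        rng = np.random.default_rng(99)
        from diffsem.simulate import _draw_weights

        w = _draw_weights(100_000, rng)
        assert abs(np.abs(w).mean() - 0.75) < 0.01
        assert abs((w < 0).mean() - 0.5) < 0.02


class TestCondition2Weights:
    def _pair(self, seed, frac=0.1):
        rng = np.random.default_rng(seed)
        A1 = generate_adjacency(15, 2, "dag", rng)
        A2, removed, added = perturb_adjacency(A1, frac, rng)
        B1 = weights_from_adjacency(A1, rng)
        return rng, A1, A2, B1, removed, added

    def test_unchanged_when_no_perturbation(self):
        rng, A1, A2, B1, _, _ = self._pair(0, frac=0.0)
        B2, reweighted = derive_condition2_weights(A2, B1, 0, rng)
        assert np.array_equal(B1.entries, B2.entries)
        assert reweighted == []

    def test_exactly_nc_shared_edges_redrawn(self):
        rng, A1, A2, B1, removed, added = self._pair(1)
        n_c = len(removed)
        B2, reweighted = derive_condition2_weights(A2, B1, n_c, rng)
        shared = (A1.entries == 1) & (A2.entries == 1)
        changed_shared = shared & (B1.entries != B2.entries)
        assert changed_shared.sum() == n_c
        assert len(reweighted) == n_c

    def test_delta_support_accounting(self):
        rng, A1, A2, B1, removed, added = self._pair(2)
        n_c = len(removed)
        B2, reweighted = derive_condition2_weights(A2, B1, n_c, rng)
        n_delta = (B1.entries != B2.entries).sum()
        # topology flips plus re-weighted shared edges (continuous draws
        # never coincide)
        assert n_delta == len(removed) + len(added) + len(reweighted)

    def test_nc_exceeding_shared_edges_rejected(self):
        rng, _, A2, B1, _, _ = self._pair(3)
        with pytest.raises(ValueError):
            derive_condition2_weights(A2, B1, 10_000, rng)


class TestGenotypes:
    def test_f2_marginals_and_support(self):
        rng = np.random.default_rng(11)
        X = simulate_genotypes(1000, 100, rng)
        assert set(np.unique(X)) <= {1.0, 2.0, 3.0}
        freqs = [(X == v).mean() for v in (1, 2, 3)]
        for f, expected in zip(freqs, (0.25, 0.5, 0.25)):
            assert abs(f - expected) < 0.01
        assert abs(X.mean() - 2.0) < 0.01

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            simulate_genotypes(0, 5, np.random.default_rng(0))


class TestEQTLMap:
    @pytest.mark.parametrize("p", [3, 10, 30])
    def test_permuted_identity_stack_structure(self, p, rng):
        F = build_eqtl_effects(p, rng)
        assert F.effects.shape == (2 * p, p)
        assert np.all(F.effects.sum(axis=1) == 1)  # one gene per eQTL
        assert np.all(F.effects.sum(axis=0) == 2)  # two eQTLs per gene
        flat = [s for sup in F.supports for s in sup]
        assert len(flat) == len(set(flat))  # disjoint supports


class TestExpression:
    def test_no_network_no_noise_reduces_to_perturbation(self, rng):
        p = 4
        A = GRNAdjacency(np.zeros((p, p), dtype=np.int8), "dag")
        B = weights_from_adjacency(A, rng)
        F = build_eqtl_effects(p, rng)
        X = simulate_genotypes(20, 2 * p, rng)
        Y = simulate_expression(B, F, X, 0.0, rng)
        np.testing.assert_allclose(Y, X @ F.effects, atol=1e-12)

    def test_sem_identity_and_noise_variance(self):
        rng = np.random.default_rng(21)
        data, truth = simulate_paired_dataset(
            p=8, n=2000, n_e=1, sigma2=0.01, kind="dag", rng=rng
        )
        for Y, X, B in [
            (data.Y1, data.X1, truth.B1),
            (data.Y2, data.X2, truth.B2),
        ]:
            resid = Y - Y @ B.entries - X @ truth.F.effects
            # residual equals E: finite but with the right variance
            assert abs(resid.var() - 0.01) < 0.002

    def test_singular_network_raises(self, rng):
        B = GRNWeights(
            np.array([[0.0, 1.0], [1.0, 0.0]]),
            GRNAdjacency(np.array([[0, 1], [1, 0]], dtype=np.int8), "dcg"),
        )
        F = build_eqtl_effects(2, rng)
        X = simulate_genotypes(5, 4, rng)
        with pytest.raises(np.linalg.LinAlgError):
            simulate_expression(B, F, X, 0.0, rng)


class TestPairedDataset:
    def test_shapes_and_delta_support(self, small_dataset):
        data, truth = small_dataset
        assert data.Y1.shape == (80, 5)
        assert data.X1.shape == (80, 10)
        assert truth.B1.entries.shape == (5, 5)
        assert len(truth.delta_support) > 0
        assert truth.delta_support == {
            tuple(c) for c in np.argwhere(truth.B1.entries != truth.B2.entries)
        }

    def test_seeded_determinism(self):
        d1, t1 = simulate_paired_dataset(
            p=6, n=30, n_e=1, sigma2=0.01, rng=np.random.default_rng(5)
        )
        d2, t2 = simulate_paired_dataset(
            p=6, n=30, n_e=1, sigma2=0.01, rng=np.random.default_rng(5)
        )
        np.testing.assert_array_equal(d1.Y1, d2.Y1)
        np.testing.assert_array_equal(d1.X2, d2.X2)
        np.testing.assert_array_equal(t1.B2.entries, t2.B2.entries)

    def test_unequal_sample_sizes_rejected(self, small_dataset):
        from diffsem.simulate import PairedDataset

        data, _ = small_dataset
        with pytest.raises(ValueError, match="paired sample size"):
            PairedDataset(
                Y1=data.Y1,
                Y2=data.Y2[:-1],
                X1=data.X1,
                X2=data.X2[:-1],
                supports=data.supports,
            )
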