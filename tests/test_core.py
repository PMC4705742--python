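import numpy as np
import pytest

from erable.core import (
    GeneMatrix,
    SolverConfig,
    assemble,
    check_identifiability,
    pair_weight,
    rescale,
    run,
    solve_constrained,
    wls_single,
    z_value,
)
from erable.distmat import DistanceMatrix
from erable.errors import DegenerateSystemError, GeneRejectedError, TreeError
from erable.tree import parse_newick

from helpers import dense_kkt_solve, random_instance, weighted_design_lstsq


def _edge_by_split(tree, side):
    """Edge id whose bipartition separates exactly `side` from the rest."""
    target = frozenset(side)
    for eid, split in tree.bipartitions().items():
        if split == target or split == tree.leaves - target:
            return eid
    raise AssertionError(f"no edge with split {side}")


class TestWeightsAndZ:
    def test_seqlen_weights(self, quartet_dm):
        g = GeneMatrix("g", 100, quartet_dm)
        w = pair_weight(g, "seqlen")
        off = ~np.eye(4, dtype=bool)
        assert np.all(w[off] == 100)
        assert np.all(np.diag(w) == 0)

    def test_flat_weights(self, quartet_dm):
        w = pair_weight(GeneMatrix("g", 100, quartet_dm), "flat")
        assert np.all(w[~np.eye(4, dtype=bool)] == 1)

    def test_undefined_pair_gets_zero_weight(self, quartet_dm):
        vals = quartet_dm.values.copy()
        vals[0, 1] = vals[1, 0] = np.nan
        g = GeneMatrix("g", 100, DistanceMatrix(quartet_dm.taxa, vals))
        w = pair_weight(g, "seqlen")
        assert w[0, 1] == 0 and w[1, 0] == 0

    def test_custom_weights_validated(self, quartet_dm):
        g = GeneMatrix("g", 100, quartet_dm)
        with pytest.raises(ValueError):
            pair_weight(g, "custom")

    def test_z_modes(self, quartet_dm):
        g = GeneMatrix("g", 100, quartet_dm)
        assert z_value(g, "unit") == 1.0
        assert z_value(g, "seqlen") == 100.0
        # sum of the six quartet distances 3+8+9+9+10+9 = 48
        assert z_value(g, "seqlen_distsum") == pytest.approx(4800.0)

    def test_all_zero_gene_rejected_for_distsum(self, quartet_dm):
        g = GeneMatrix("g", 100, DistanceMatrix(quartet_dm.taxa,
                                                np.zeros((4, 4))))
        with pytest.raises(GeneRejectedError):
            z_value(g, "seqlen_distsum")


class TestAssemble:
    def test_quadratic_pieces(self, quartet, quartet_dm):
        g = GeneMatrix("g", 100, quartet_dm)
        internals = assemble([g], quartet, SolverConfig(weight_mode="flat"))
        # S = 3^2+8^2+9^2+9^2+10^2+9^2 = 416
        assert internals.S[0] == pytest.approx(416.0)
        # pairs crossing the internal edge: AC, AD, BC, BD -> 8+9+9+10 = 36
        internal = _edge_by_split(quartet, {"A", "B"})
        assert internals.U[0, internal] == pytest.approx(36.0)
        # pendant edge of A is used by the 3 pairs containing A (flat weights)
        pend_a = _edge_by_split(quartet, {"A"})
        assert internals.H[pend_a, pend_a] == pytest.approx(3.0)

    def test_unknown_taxon_names_gene(self, quartet):
        dm = DistanceMatrix(["A", "B", "Z"], [[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        with pytest.raises(TreeError, match="bad_gene.*Z"):
            assemble([GeneMatrix("bad_gene", 50, dm)], quartet)


class TestSolve:
    def test_single_matrix_exact_fit(self, quartet, quartet_dm):
        res = run([GeneMatrix("g", 300, quartet_dm)], quartet)
        assert res.alpha_hat[0] == pytest.approx(1.0, abs=1e-10)
        assert res.Q_value == pytest.approx(0.0, abs=1e-8)
        assert sorted(res.tree.edge_lengths) == pytest.approx([1, 2, 3, 4, 5])

    def test_two_gene_closed_form(self, quartet, two_genes):
        res = run(two_genes, quartet)
        assert res.alpha_hat == pytest.approx([2.0, 2 / 3], abs=1e-9)
        assert res.c == pytest.approx(1.0, abs=1e-9)
        assert res.rates == pytest.approx([0.5, 1.5], abs=1e-9)
        assert sorted(res.tree.edge_lengths) == pytest.approx(
            [2, 4, 6, 8, 10], abs=1e-8
        )
        assert res.Q_value == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_kkt_oracle(self, seed):
        genes, topo = random_instance(seed, n_max=12, m_max=20)
        internals = solve_constrained(assemble(genes, topo))
        b, alpha, lam = dense_kkt_solve(internals)
        assert internals.b_hat == pytest.approx(b, abs=1e-8)
        assert internals.alpha_hat == pytest.approx(alpha, abs=1e-8)
        assert internals.lam == pytest.approx(lam, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_constraint_satisfied(self, seed):
        genes, topo = random_instance(seed)
        internals = solve_constrained(assemble(genes, topo))
        lhs = float(internals.Z @ internals.alpha_hat)
        assert lhs == pytest.approx(internals.rhs, rel=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_solution_is_the_constrained_minimum(self, seed):
        genes, topo = random_instance(seed, n_max=10, m_max=10)
        internals = solve_constrained(assemble(genes, topo))
        rng = np.random.default_rng(seed)
        b0, a0 = internals.b_hat, internals.alpha_hat
        Z, S, U, H = internals.Z, internals.S, internals.U, internals.H

        def q(alpha, b):
            return float(S @ alpha**2 - 2 * alpha @ (U @ b) + b @ H @ b)

        q_star = q(a0, b0)
        for _ in range(200):
            da = rng.standard_normal(len(a0)) * 0.05
            da -= Z * (Z @ da) / (Z @ Z)  # stay on the constraint hyperplane
            db = rng.standard_normal(len(b0)) * 0.05
            assert q(a0 + da, b0 + db) >= q_star - 1e-9

    def test_stationarity_residuals(self, two_genes, quartet):
        internals = solve_constrained(assemble(two_genes, quartet))
        grad_b = 2 * internals.H @ internals.b_hat - 2 * (
            internals.alpha_hat @ internals.U
        )
        grad_a = (
            2 * internals.S * internals.alpha_hat
            - 2 * internals.U @ internals.b_hat
            + internals.lam * internals.Z
        )
        scale = max(1.0, float(np.abs(internals.U).max()))
        assert np.abs(grad_b).max() < 1e-8 * scale
        assert np.abs(grad_a).max() < 1e-8 * scale


class TestRescale:
    def test_correction_factor_arithmetic(self, two_genes, quartet):
        # c = (1/200)(100/2 + 100/(2/3)) = 1
        res = run(two_genes, quartet)
        assert res.c == pytest.approx(1.0, abs=1e-9)

    def test_all_alpha_one_means_no_correction(self, quartet, quartet_dm):
        res = run([GeneMatrix("g", 123, quartet_dm)], quartet)
        assert res.c == pytest.approx(1.0, abs=1e-9)
        assert res.rates == pytest.approx([1.0], abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_weighted_mean_rate_is_one(self, seed):
        genes, topo = random_instance(seed)
        res = run(genes, topo)
        if (res.alpha_hat > 0).all():
            mean = float(res.n_sites @ res.rates / res.n_sites.sum())
            assert mean == pytest.approx(1.0, abs=1e-9)

    def test_negative_length_clamping(self):
        topo = parse_newick("((A:1,B:1):1,(C:1,D:1));")
        dm = topo.patristic_matrix()
        vals = dm.values.copy()
        ia, ib = dm.index("A"), dm.index("B")
        vals[ia, ib] = vals[ib, ia] = 6.0  # stretches the cherry, internal < 0
        g = GeneMatrix("g", 100, DistanceMatrix(dm.taxa, vals))
        res = run([g], topo)
        assert (res.tree.edge_lengths < 0).any()
        assert any("negative branch" in w for w in res.warnings)
        clamped = run([g], topo, SolverConfig(clamp_negative_lengths=True))
        assert (clamped.tree.edge_lengths >= 0).all()


class TestInvariances:
    def test_rhs_scale_is_irrelevant(self, two_genes, quartet):
        a = run(two_genes, quartet, SolverConfig(rhs_scale=1.0))
        b = run(two_genes, quartet, SolverConfig(rhs_scale=1000.0))
        assert a.rates == pytest.approx(b.rates, rel=1e-10)
        assert a.tree.edge_lengths == pytest.approx(
            b.tree.edge_lengths, rel=1e-10
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_global_distance_scaling_covariance(self, seed):
        genes, topo = random_instance(seed)
        gamma = 3.7
        scaled = [
            GeneMatrix(g.name, g.n_sites,
                       DistanceMatrix(g.delta.taxa, gamma * g.delta.values))
            for g in genes
        ]
        a, b = run(genes, topo), run(scaled, topo)
        assert b.rates == pytest.approx(a.rates, rel=1e-9)
        assert b.tree.edge_lengths == pytest.approx(
            gamma * a.tree.edge_lengths, rel=1e-9
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_single_gene_reduction_equals_wls(self, seed):
        genes, topo = random_instance(seed, full_overlap=True)
        g = genes[0]
        w = pair_weight(g, "seqlen")
        direct = wls_single(g.delta, w, topo)
        res = run([g], topo)
        assert res.tree.edge_lengths == pytest.approx(direct, abs=1e-10)
        # and both equal a generic design-matrix least-squares fit
        oracle = weighted_design_lstsq(g.delta, w, topo)
        assert direct == pytest.approx(oracle, abs=1e-8)


class TestIdentifiability:
    @pytest.fixture()
    def octet(self):
        return parse_newick(
            "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
        )

    def test_disjoint_quartets_are_non_unique(self, octet):
        g1 = GeneMatrix("q1", 100,
                        octet.restrict("ABCD").patristic_matrix())
        g2 = GeneMatrix("q2", 100,
                        octet.restrict("EFGH").patristic_matrix())
        report = check_identifiability([g1, g2], octet)
        assert len(report.non_cooccurring_pairs) == 16
        assert report.rank_deficient and not report.unique
        # the bridge between the quartets is among the unconstrained edges
        bridge = _edge_by_split(octet, {"A", "B", "C", "D"})
        assert bridge in report.null_space_edges
        res = run([g1, g2], octet)
        assert not res.unique

    def test_full_overlap_is_unique(self, octet):
        g = GeneMatrix("g", 100, octet.patristic_matrix())
        report = check_identifiability([g], octet)
        assert report.non_cooccurring_pairs == ()
        assert report.unique

    def test_chained_overlap_missing_pair_but_unique(self):
        # necessary-not-sufficient: (A,E) never co-occur, yet the optimum
        # is unique because the two genes chain through B, C, D
        topo = parse_newick("((A:1,B:1):1,(C:1,(D:1,E:1):1):1);")
        g1 = GeneMatrix("g1", 100,
                        topo.restrict("ABCD").patristic_matrix())
        g2 = GeneMatrix("g2", 100,
                        topo.restrict("BCDE").patristic_matrix())
        report = check_identifiability([g1, g2], topo)
        assert ("A", "E") in report.non_cooccurring_pairs
        assert report.unique


class TestRejection:
    def test_no_positive_pair(self, quartet):
        vals = np.full((4, 4), np.nan)
        np.fill_diagonal(vals, 0.0)
        dm = DistanceMatrix(list("ABCD"), vals)
        with pytest.raises(GeneRejectedError):
            run([GeneMatrix("empty", 100, dm)], quartet)

    def test_no_genes(self, quartet):
        with pytest.raises(GeneRejectedError):
            assemble([], quartet)

    def test_rescale_requires_solution(self, two_genes, quartet):
        internals = assemble(two_genes, quartet)
        with pytest.raises(ValueError):
            rescale(internals)
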