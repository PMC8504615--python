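import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarebic import (
    ExpressionMatrix,
    SearchParams,
    gene_stats,
    negative_fraction,
    objective,
    select_genes,
)
from rarebic.core import (
    exhaustive_gene_subsets,
    select_genes_from_stats,
)


def _m(rows, **kw):
    return ExpressionMatrix(np.asarray(rows, dtype=float), normalized=True, **kw)


class TestGeneStats:
    def test_hand_evaluated_inner_term(self):
        M = _m([[2, 1, -1, 3]])
        s = gene_stats(M, "g1", ["c1", "c2"], kappa=1.0)
        assert (s.in_sum, s.out_pos, s.neg_count, s.gain) == (3.0, 3.0, 0, 0.0)

    def test_all_cells_has_no_out_of_cluster_mass(self):
        M = _m([[2, 1, -1, 3]])
        s = gene_stats(M, "g1", M.cell_names, kappa=5.0)
        assert s.out_pos == 0.0
        assert s.gain == s.in_sum == 5.0

    def test_kappa_zero_ignores_out_of_cluster(self):
        M = _m([[2, 1, -1, 3]])
        s = gene_stats(M, "g1", ["c3"], kappa=0.0)
        assert s.gain == s.in_sum == -1.0
        assert s.neg_count == 1

    def test_unknown_identifiers_raise(self):
        M = _m([[1, 2]])
        with pytest.raises(KeyError):
            gene_stats(M, "nope", ["c1"], 1.0)
        with pytest.raises(KeyError):
            gene_stats(M, "g1", ["c9"], 1.0)


class TestObjective:
    def test_empty_gene_set_is_zero(self):
        M = _m([[1, 1, -2]])
        assert objective(M, [], ["c1"], 1.0) == 0.0

    def test_hand_evaluated_two_gene_value(self):
        M = _m([[1, 1, -2], [2, -1, 1]])
        val = objective(M, ["g1", "g2"], ["c1", "c2"], kappa=0.5)
        assert val == pytest.approx(2.5)

    @settings(max_examples=30, deadline=None)
    @given(scale=st.floats(0.1, 10), seed=st.integers(0, 100))
    def test_positive_scaling_scales_objective(self, scale, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(-2, 2, size=(4, 5))
        base = objective(_m(vals), ["g1", "g3"], ["c2", "c4"], 0.7)
        scaled = objective(_m(vals * scale), ["g1", "g3"], ["c2", "c4"], 0.7)
        assert scaled == pytest.approx(base * scale, rel=1e-9)


class TestNegativeFraction:
    def test_all_positive_block_is_zero(self):
        M = _m([[1, 2], [3, 4]])
        assert negative_fraction(M, ["g1", "g2"], ["c1", "c2"]) == 0.0

    def test_direct_count(self):
        M = _m([[1, 2, -1], [3, 4, 5]])
        frac = negative_fraction(M, ["g1", "g2"], ["c1", "c2", "c3"])
        assert frac == pytest.approx(1 / 6)

    def test_exact_zero_entry_is_not_negative(self):
        M = _m([[0.0, 1.0]])
        assert negative_fraction(M, ["g1"], ["c1", "c2"]) == 0.0

    def test_empty_sets_rejected(self):
        M = _m([[1.0]])
        with pytest.raises(ValueError):
            negative_fraction(M, [], ["c1"])
        with pytest.raises(ValueError):
            negative_fraction(M, ["g1"], [])


class TestSelectGenes:
    def test_unconstrained_keeps_only_strictly_positive_gains(self):
        sel, obj = select_genes_from_stats(
            np.array([3.0, 0.0, -1.0]), np.array([0, 0, 0]), n_cells=2, mu=1.0
        )
        assert list(sel) == [0]
        assert obj == 3.0

    def test_constrained_prefix_matches_exhaustive_on_worked_example(self):
        # genes (gain, neg_count): gA (5,1), gB (4,0), gC (3,1); 2 cells, mu=0.25
        gain = np.array([5.0, 4.0, 3.0])
        neg = np.array([1, 0, 1])
        sel, obj = select_genes_from_stats(gain, neg, n_cells=2, mu=0.25)
        assert set(sel) == {0, 1}
        assert obj == 9.0
        brute_sel, brute_obj = exhaustive_gene_subsets(gain, neg, 0.25, 2)
        assert brute_obj == 9.0
        assert set(brute_sel) == {0, 1}

    def test_all_negative_gains_yield_empty_invalid_candidate(self):
        sel, obj = select_genes_from_stats(
            np.array([-1.0, -2.0]), np.array([0, 0]), n_cells=3, mu=0.5
        )
        assert sel.size == 0
        assert obj == 0.0

    def test_matrix_level_wrapper_respects_min_cells(self):
        M = _m(np.ones((3, 4)))
        with pytest.raises(ValueError, match="min_cells"):
            select_genes(M, ["c1"], SearchParams())

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_matches_full_enumeration_and_bounds_heuristic(self, seed):
        rng = np.random.default_rng(seed)
        n_genes, n_cells = 10, 4
        gain = np.round(rng.uniform(-2, 5, n_genes), 2)
        neg = rng.integers(0, n_cells + 1, n_genes)
        mu = float(rng.choice([0.1, 0.25, 0.5]))
        _, exact_obj = select_genes_from_stats(gain, neg, n_cells, mu, exact=True)
        _, brute_obj = exhaustive_gene_subsets(gain, neg, mu, n_cells)
        _, heur_obj = select_genes_from_stats(gain, neg, n_cells, mu)
        assert exact_obj == pytest.approx(brute_obj)
        assert heur_obj <= exact_obj + 1e-12

    def test_selected_set_shrinks_as_kappa_grows(self):
        rng = np.random.default_rng(7)
        M = _m(np.round(rng.uniform(-2, 3, size=(12, 6)), 2))
        J = ["c1", "c2", "c3"]
        previous = None
        for kappa in [0.0, 0.25, 0.5, 1.0, 2.0, 5.0]:
            sel, _ = select_genes(M, J, SearchParams(kappa=kappa, mu=1.0))
            current = set(sel)
            if previous is not None:
                assert current <= previous
            previous = current

    def test_heuristic_solution_always_feasible(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n_cells = int(rng.integers(2, 6))
            gain = rng.uniform(-1, 4, 15)
            neg = rng.integers(0, n_cells + 1, 15)
            mu = float(rng.uniform(0, 0.5))
            sel, _ = select_genes_from_stats(gain, neg, n_cells, mu)
            if sel.size:
                assert neg[sel].sum() <= mu * sel.size * n_cells + 1e-9
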