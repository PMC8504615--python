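import numpy as np
import pytest

from rarebic import (
    ExpressionMatrix,
    SearchParams,
    beam_search,
    evaluate_candidate,
    exhaustive_search,
    negative_fraction,
    objective,
    top_k,
)
from rarebic.toy import TOY_CELLS, TOY_GENES, toy_matrix


def _m(rows, **kw):
    return ExpressionMatrix(np.asarray(rows, dtype=float), normalized=True, **kw)


def planted_20x10():
    """Rows 1-5 are +2 on cells 1-3 and -1 elsewhere; rest all -1."""
    vals = -np.ones((20, 10))
    vals[:5, :3] = 2.0
    return ExpressionMatrix(vals, normalized=True)


class TestEvaluateCandidate:
    def test_negative_gain_cell_set_is_invalid(self):
        M = _m(-np.ones((4, 5)))
        assert evaluate_candidate(M, ["c1", "c2"], SearchParams(kappa=1.0)) is None

    def test_two_identical_positive_columns(self):
        M = _m([[3, 3, 1, 0]])
        bc = evaluate_candidate(M, ["c1", "c2"], SearchParams(kappa=1.0, mu=1.0))
        assert bc.genes == ["g1"]
        # 2 * 3 - kappa * remaining positive mass (1)
        assert bc.objective == pytest.approx(5.0)

    def test_planted_block_recovers_its_genes(self):
        bc = evaluate_candidate(
            planted_20x10(), ["c1", "c2", "c3"], SearchParams(kappa=1.0, mu=0.1)
        )
        assert bc.genes == ["g1", "g2", "g3", "g4", "g5"]
        assert bc.objective == pytest.approx(30.0)


class TestBeamSearch:
    def test_planted_block_is_global_optimum(self):
        params = SearchParams(kappa=1.0, mu=0.1)
        res = beam_search(planted_20x10(), params)
        oracle = exhaustive_search(planted_20x10(), params)
        assert res.found and oracle.found
        assert sorted(res.bicluster.cells) == ["c1", "c2", "c3"]
        assert sorted(res.bicluster.genes) == ["g1", "g2", "g3", "g4", "g5"]
        assert res.bicluster.objective == pytest.approx(30.0)
        assert oracle.bicluster.objective == pytest.approx(30.0)

    def test_toy_worked_example_three_cells_five_genes(self):
        res = beam_search(toy_matrix(), SearchParams(kappa=1.0, mu=0.1))
        assert sorted(res.bicluster.cells) == TOY_CELLS
        assert sorted(res.bicluster.genes) == sorted(TOY_GENES)

    @pytest.mark.parametrize("seed", [1, 7, 23])
    def test_unlimited_width_matches_exhaustive(self, random_signed_matrix, seed):
        M = random_signed_matrix(seed, n_genes=15, n_cells=8)
        params = SearchParams(kappa=1.0, mu=0.1)
        oracle = exhaustive_search(M, params)
        wide = SearchParams(
            kappa=1.0, mu=0.1, beam_width=2 ** M.n_cells, patience=M.n_cells
        )
        res = beam_search(M, wide)
        assert res.found == oracle.found
        if oracle.found:
            assert res.bicluster.objective == pytest.approx(
                oracle.bicluster.objective
            )

    def test_deterministic(self, random_signed_matrix):
        M = random_signed_matrix(3)
        p = SearchParams(kappa=0.5, mu=0.2)
        a = beam_search(M, p)
        b = beam_search(M, p)
        assert a.bicluster.cells == b.bicluster.cells
        assert a.bicluster.genes == b.bicluster.genes
        assert a.n_evaluations == b.n_evaluations

    def test_label_equivariance_under_permutation(self, random_signed_matrix):
        M = random_signed_matrix(5, n_genes=12, n_cells=7)
        rng = np.random.default_rng(0)
        gp, cp = rng.permutation(12), rng.permutation(7)
        P = ExpressionMatrix(
            M.values[np.ix_(gp, cp)],
            gene_names=[M.gene_names[i] for i in gp],
            cell_names=[M.cell_names[j] for j in cp],
            normalized=True,
        )
        p = SearchParams(kappa=1.0, mu=0.1)
        a, b = beam_search(M, p), beam_search(P, p)
        assert set(a.bicluster.cells) == set(b.bicluster.cells)
        assert set(a.bicluster.genes) == set(b.bicluster.genes)
        assert a.bicluster.objective == pytest.approx(b.bicluster.objective)

    def test_incremental_stats_agree_with_fresh_recomputation(
        self, random_signed_matrix
    ):
        M = random_signed_matrix(9)
        params = SearchParams(kappa=0.8, mu=0.15)
        res = beam_search(M, params)
        bc = res.bicluster
        # evaluate_candidate recomputes the stats from scratch
        fresh = evaluate_candidate(M, bc.cells, params)
        assert fresh.genes == bc.genes
        assert fresh.objective == pytest.approx(bc.objective)
        # and the per-gene definition agrees entry for entry
        assert objective(M, bc.genes, bc.cells, 0.8) == pytest.approx(bc.objective)

    def test_no_solution_is_explicit_not_an_exception(self):
        M = _m(-np.ones((5, 6)))
        res = beam_search(M, SearchParams(kappa=1.0))
        assert not res.found
        assert res.bicluster is None
        assert "no feasible" in res.message

    def test_returned_bicluster_respects_constraints(self, random_signed_matrix):
        for seed in range(5):
            M = random_signed_matrix(seed + 40)
            params = SearchParams(kappa=1.0, mu=0.1)
            res = beam_search(M, params)
            if res.found:
                bc = res.bicluster
                assert bc.n_cells >= 2
                assert negative_fraction(M, bc.genes, bc.cells) <= 0.1 + 1e-12


class TestExhaustiveSearch:
    def test_tiny_brute_force_instance(self):
        M = _m([[1, 1, -5]])
        res = exhaustive_search(M, SearchParams(kappa=0.0, mu=1.0))
        assert sorted(res.bicluster.cells) == ["c1", "c2"]
        assert res.bicluster.genes == ["g1"]
        assert res.bicluster.objective == pytest.approx(2.0)

    def test_all_negative_matrix_has_no_solution(self):
        res = exhaustive_search(_m(-np.ones((3, 4))), SearchParams(kappa=1.0))
        assert not res.found

    def test_guard_refuses_large_instances(self):
        M = _m(np.ones((2, 21)))
        with pytest.raises(ValueError, match="guard"):
            exhaustive_search(M, SearchParams())

    def test_tie_break_prefers_smaller_lexicographic_cell_sets(self):
        # two identical positive columns twice: both pairs score equally
        M = _m([[2, 2, 2, 2]])
        res = exhaustive_search(M, SearchParams(kappa=0.0, mu=1.0, max_cells=2))
        assert res.bicluster.cells == ["c1", "c2"]


class TestTopK:
    def test_k1_identical_to_beam_search(self, random_signed_matrix):
        M = random_signed_matrix(13)
        params = SearchParams(kappa=1.0, mu=0.1)
        single = beam_search(M, params).bicluster
        [only] = top_k(M, params, 1)
        assert only.cells == single.cells
        assert only.genes == single.genes

    def test_two_disjoint_planted_blocks_both_recovered(self):
        vals = -np.ones((20, 12))
        vals[:5, :3] = 2.0    # block A: genes 1-5, cells 1-3
        vals[5:10, 3:6] = 2.0  # block B: genes 6-10, cells 4-6
        M = ExpressionMatrix(vals, normalized=True)
        params = SearchParams(kappa=1.0, mu=0.1, max_prevalence=1.0)
        blocks = top_k(M, params, 2)
        assert len(blocks) == 2
        found = [set(b.cells) for b in blocks]
        assert {"c1", "c2", "c3"} in found
        assert {"c4", "c5", "c6"} in found
        assert found[0].isdisjoint(found[1])

    def test_matrix_exhausted_returns_short_list(self):
        vals = -np.ones((6, 4))
        vals[:3, :3] = 2.0
        M = ExpressionMatrix(vals, normalized=True)
        blocks = top_k(M, SearchParams(kappa=1.0, mu=0.1, max_prevalence=1.0), 3)
        assert len(blocks) == 1  # 1 cell left after round one

    def test_evaluation_count_scales_with_beam_budget(self, random_signed_matrix):
        M = random_signed_matrix(2, n_genes=20, n_cells=10)
        params = SearchParams(kappa=1.0, mu=0.1, beam_width=5)
        res = beam_search(M, params)
        n = M.n_cells
        assert res.n_evaluations <= params.beam_width * n * n
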