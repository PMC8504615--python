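"""Objective, constraint and fixed-cell-set gene optimization.

For a bicluster (I, J) of genes I and cells J the objective is

    f(I, J) = sum_{i in I} [ sum_{j in J} m_ij  -  kappa * sum_{k not in J} max(0, m_ik) ]

i.e. the in-cluster sum minus a kappa-weighted penalty on out-of-cluster
expression of the selected genes, subject to the sparsity constraint

    #{(i, j) in I x J : m_ij < 0}  <=  mu * |I| * |J|.

The objective is additive over genes, so for a fixed cell set J the
unconstrained (mu = 1) optimum over genes is simply every gene whose
per-gene gain is strictly positive — found in linear time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .matrix import ExpressionMatrix

#: largest candidate-gene count accepted by the exact constrained selection
EXACT_GENE_LIMIT = 22


@dataclass
class SearchParams:
    """Tunable parameters of the bicluster search.

    kappa : out-of-cluster penalty weight; None means the default 100/|C|,
        resolved against the matrix at search time.  Higher kappa, fewer
        and more specific genes.
    mu : allowed fraction of negative entries inside the bicluster
        (default 10%); tolerates dropout zeros among true cluster cells.
    max_prevalence : gene prevalence filter threshold (default 25%).
    min_cells / max_cells : bicluster size bounds on the cell axis.
    beam_width : frontier size of the breadth-first search.
    patience : levels without improvement before the search stops.
    top_k : how many disjoint biclusters the iterated strategy extracts.
    """

    kappa: float | None = None
    mu: float = 0.1
    max_prevalence: float = 0.25
    min_cells: int = 2
    max_cells: int | None = None
    beam_width: int = 100
    patience: int = 2
    top_k: int = 1
    exact_genes: bool = False

    def __post_init__(self) -> None:
        if self.kappa is not None and self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        if not 0 <= self.mu <= 1:
            raise ValueError(f"mu must be in [0, 1], got {self.mu}")
        if self.min_cells < 2:
            raise ValueError(f"min_cells must be >= 2, got {self.min_cells}")
        if self.max_cells is not None and self.max_cells < self.min_cells:
            raise ValueError("max_cells must be >= min_cells")
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    def resolve_kappa(self, n_cells: int) -> float:
        """The recommended default is 100 / |C| when unset."""
        return 100.0 / n_cells if self.kappa is None else self.kappa


@dataclass
class GeneStats:
    """Per-gene sufficient statistics for a fixed cell set J."""

    in_sum: float
    out_pos: float
    neg_count: int
    gain: float


@dataclass
class Bicluster:
    """A selected gene set I and cell set J with its objective value."""

    genes: list[str]
    cells: list[str]
    objective: float
    negative_fraction: float
    gene_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    cell_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _as_cell_indices(M: ExpressionMatrix, J) -> np.ndarray:
    J = list(J)
    if J and isinstance(J[0], str):
        return M.cell_indices(J)
    return np.asarray(J, dtype=int)


def gene_stats(
    M: ExpressionMatrix, gene: str | int, J, kappa: float
) -> GeneStats:
    """Sufficient statistics of one gene for cell set J.

    in_sum is the sum of the gene's values over J; out_pos the positive
    mass of the gene outside J; gain = in_sum - kappa * out_pos is the
    gene's additive contribution to the objective.
    """
    jdx = _as_cell_indices(M, J)
    if jdx.size == 0:
        raise ValueError("J must be non-empty")
    if np.any(jdx < 0) or np.any(jdx >= M.n_cells):
        raise KeyError("cell index out of range")
    gi = M.gene_index(gene) if isinstance(gene, str) else int(gene)
    if not 0 <= gi < M.n_genes:
        raise KeyError(f"gene index {gi} out of range")
    row = M.values[gi]
    mask = np.zeros(M.n_cells, dtype=bool)
    mask[jdx] = True
    in_sum = float(row[mask].sum())
    out_pos = float(np.clip(row[~mask], 0, None).sum())
    neg_count = int((row[mask] < 0).sum())
    return GeneStats(in_sum, out_pos, neg_count, in_sum - kappa * out_pos)


def objective(M: ExpressionMatrix, I, J, kappa: float) -> float:
    """f(I, J): sum over genes in I of the per-gene gain.  Empty I -> 0."""
    I = list(I)
    if not I:
        return 0.0
    return float(sum(gene_stats(M, g, J, kappa).gain for g in I))


def negative_fraction(M: ExpressionMatrix, I, J) -> float:
    """Fraction of strictly negative entries inside the bicluster I x J.

    Entries exactly zero are not negative.  Feasibility under the
    sparsity constraint is ``negative_fraction <= mu`` (inclusive).
    """
    I = list(I)
    jdx = _as_cell_indices(M, J)
    if not I or jdx.size == 0:
        raise ValueError("negative_fraction is undefined for empty I or J")
    idx = np.array(
        [M.gene_index(g) if isinstance(g, str) else int(g) for g in I], dtype=int
    )
    block = M.values[np.ix_(idx, jdx)]
    return float((block < 0).sum() / block.size)


# ---------------------------------------------------------------------------
# Fixed-cell-set gene optimization


def _gene_stat_arrays(values: np.ndarray, jdx: np.ndarray, kappa: float):
    """Vectorized per-gene (gain, neg_count) for the cell set ``jdx``."""
    sub = values[:, jdx]
    in_sum = sub.sum(axis=1)
    in_pos = np.clip(sub, 0, None).sum(axis=1)
    total_pos = np.clip(values, 0, None).sum(axis=1)
    out_pos = total_pos - in_pos
    gain = in_sum - kappa * out_pos
    neg_count = (sub < 0).sum(axis=1)
    return gain, neg_count


def _longest_feasible_prefix(
    order: np.ndarray, gain: np.ndarray, neg: np.ndarray, mu: float, n_cells: int
) -> np.ndarray:
    """Longest prefix of ``order`` whose negative-entry fraction is <= mu.

    ``order`` sorts candidates by ascending neg_count, so prefix means of
    neg are non-decreasing: feasibility of prefixes is monotone and the
    longest feasible prefix is well defined.
    """
    cum_neg = np.cumsum(neg[order])
    sizes = np.arange(1, order.size + 1)
    feasible = cum_neg <= mu * sizes * n_cells + 1e-9
    if not feasible.any():
        return order[:0]
    last = int(np.max(np.flatnonzero(feasible)))
    return order[: last + 1]


def _exact_gene_subset(
    gain: np.ndarray, neg: np.ndarray, mu: float, n_cells: int
) -> np.ndarray:
    """Exact constrained selection among positive-gain candidates.

    Depth-first branch and bound over candidates sorted by descending
    gain; the optimistic bound is the unconstrained remaining gain.
    Intended for small test instances (<= EXACT_GENE_LIMIT candidates).
    """
    n = gain.size
    order = np.lexsort((np.arange(n), -gain))
    g = gain[order]
    v = neg[order]
    suffix = np.concatenate([np.cumsum(g[::-1])[::-1], [0.0]])

    best_val = 0.0
    best_set: list[int] = []

    def recurse(pos: int, chosen: list[int], val: float, negs: int) -> None:
        nonlocal best_val, best_set
        if chosen and negs <= mu * len(chosen) * n_cells + 1e-9 and val > best_val:
            best_val = val
            best_set = chosen.copy()
        if pos == n or val + suffix[pos] <= best_val:
            return
        chosen.append(pos)
        recurse(pos + 1, chosen, val + g[pos], negs + int(v[pos]))
        chosen.pop()
        recurse(pos + 1, chosen, val, negs)

    recurse(0, [], 0.0, 0)
    return np.sort(order[np.array(best_set, dtype=int)]) if best_set else order[:0]


def select_genes_from_stats(
    gain: np.ndarray,
    neg_count: np.ndarray,
    n_cells: int,
    mu: float,
    exact: bool = False,
) -> tuple[np.ndarray, float]:
    """Optimal/heuristic gene subset from precomputed per-gene stats.

    Returns (sorted gene indices, objective).  Only strictly
    positive-gain genes are ever candidates: zero-gain genes add nothing
    but consume the mu budget, negative-gain genes lower the objective.

    mu = 1 (unconstrained): exactly {i : gain_i > 0}, the provable
    optimum since the objective is additive over genes.

    mu < 1: by default, candidates are sorted by ascending neg_count
    (ties: descending gain, then index) and the longest feasible prefix
    is returned — linear after sorting and never constraint-violating.
    With ``exact`` the selection is solved by branch and bound.
    """
    candidates = np.flatnonzero(gain > 0)
    if candidates.size == 0:
        return candidates, 0.0
    if mu >= 1:
        return candidates, float(gain[candidates].sum())
    cg = gain[candidates]
    cn = neg_count[candidates]
    if exact:
        if candidates.size > EXACT_GENE_LIMIT:
            raise ValueError(
                f"exact gene selection limited to {EXACT_GENE_LIMIT} candidates, "
                f"got {candidates.size}"
            )
        sel = _exact_gene_subset(cg, cn, mu, n_cells)
    else:
        order = np.lexsort((np.arange(candidates.size), -cg, cn))
        sel = _longest_feasible_prefix(order, cg, cn, mu, n_cells)
    chosen = candidates[np.sort(sel)]
    return chosen, float(gain[chosen].sum())


def select_genes(
    M: ExpressionMatrix,
    J,
    params: SearchParams,
    exact: bool = False,
) -> tuple[list[str], float]:
    """Best gene set for a fixed cell set J; see select_genes_from_stats."""
    jdx = _as_cell_indices(M, J)
    if jdx.size < params.min_cells:
        raise ValueError(
            f"|J| = {jdx.size} is below min_cells = {params.min_cells}"
        )
    kappa = params.resolve_kappa(M.n_cells)
    gain, neg = _gene_stat_arrays(M.values, jdx, kappa)
    idx, obj = select_genes_from_stats(gain, neg, jdx.size, params.mu, exact=exact)
    return [M.gene_names[i] for i in idx], obj


def exhaustive_gene_subsets(
    gain: np.ndarray, neg: np.ndarray, mu: float, n_cells: int
) -> tuple[np.ndarray, float]:
    """Full enumeration over all subsets of positive-gain genes.

    Test oracle for the constrained selection; exponential, keep the
    candidate count tiny (<= ~15).
    """
    candidates = np.flatnonzero(gain > 0)
    best: tuple[np.ndarray, float] = (candidates[:0], 0.0)
    for r in range(1, candidates.size + 1):
        for combo in combinations(candidates, r):
            combo = np.array(combo, dtype=int)
            if (neg[combo].sum()) <= mu * combo.size * n_cells + 1e-9:
                val = float(gain[combo].sum())
                if val > best[1]:
                    best = (combo, val)
    return best
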