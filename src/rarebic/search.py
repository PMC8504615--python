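"""Search over cell subsets: breadth-first beam heuristic, exhaustive
oracle and the iterated (top-k) extraction of disjoint biclusters.

The search exploits that for a fixed cell set the gene dimension is
solved in (near-)linear time, so only cell subsets are enumerated:
level 2 evaluates every pair of cells, and each later level grows only
the ``beam_width`` most promising frontier sets by one cell (supersets
only).  A highly specific optimum tends to score well already at small
subset sizes, which is what makes the beam cut safe in practice.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .core import (
    Bicluster,
    SearchParams,
    select_genes_from_stats,
)
from .matrix import ExpressionMatrix
from .preprocess import filter_genes

EXHAUSTIVE_CELL_GUARD = 20


@dataclass
class LevelLog:
    level: int
    n_candidates: int
    frontier_size: int
    best_objective: float


@dataclass
class SearchResult:
    """Outcome of one solver invocation.

    ``bicluster`` is None when no feasible bicluster exists (an explicit
    no-solution result, not an error); ``message`` then says why.
    """

    bicluster: Bicluster | None
    n_evaluations: int = 0
    levels: list[LevelLog] = field(default_factory=list)
    message: str = ""

    @property
    def found(self) -> bool:
        return self.bicluster is not None


class _Precomp:
    """Shared per-matrix arrays for incremental candidate evaluation."""

    def __init__(self, M: ExpressionMatrix, params: SearchParams):
        self.values = M.values
        self.pos = np.clip(M.values, 0, None)
        self.neg = (M.values < 0).astype(np.int32)
        self.total_pos = self.pos.sum(axis=1)
        self.kappa = params.resolve_kappa(M.n_cells)
        self.mu = params.mu
        self.exact = params.exact_genes
        self.n_evaluations = 0

    def stats_for(self, cells: tuple[int, ...]):
        """Per-gene (in_sum, in_pos, neg_count) recomputed from scratch."""
        idx = np.asarray(cells, dtype=int)
        sub = self.values[:, idx]
        return (
            sub.sum(axis=1),
            self.pos[:, idx].sum(axis=1),
            self.neg[:, idx].sum(axis=1),
        )

    def evaluate(self, in_sum, in_pos, neg_count, n_cells: int):
        """Gene selection + objective from sufficient statistics.

        out_pos = total_pos - in_pos, so stats of a superset J + {c} are
        the parent's stats plus column c — no rescan of J needed.
        """
        self.n_evaluations += 1
        gain = in_sum - self.kappa * (self.total_pos - in_pos)
        return select_genes_from_stats(
            gain, neg_count, n_cells, self.mu, exact=self.exact
        )


def _make_bicluster(
    M: ExpressionMatrix, gene_idx: np.ndarray, cells: tuple[int, ...], obj: float
) -> Bicluster:
    cell_idx = np.asarray(cells, dtype=int)
    block = M.values[np.ix_(gene_idx, cell_idx)]
    return Bicluster(
        genes=[M.gene_names[i] for i in gene_idx],
        cells=[M.cell_names[j] for j in cell_idx],
        objective=obj,
        negative_fraction=float((block < 0).sum() / block.size),
        gene_idx=gene_idx,
        cell_idx=cell_idx,
    )


def evaluate_candidate(
    M: ExpressionMatrix, J, params: SearchParams
) -> Bicluster | None:
    """Gene-optimize a fixed cell set; None when no gene has positive gain."""
    from .core import _as_cell_indices

    jdx = _as_cell_indices(M, J)
    if jdx.size < 2:
        raise ValueError("a candidate needs at least 2 cells")
    pre = _Precomp(M, params)
    genes, obj = pre.evaluate(*pre.stats_for(tuple(jdx)), jdx.size)
    if genes.size == 0:
        return None
    return _make_bicluster(M, genes, tuple(int(j) for j in jdx), obj)


def _within_bounds(level: int, params: SearchParams) -> bool:
    return level >= params.min_cells and (
        params.max_cells is None or level <= params.max_cells
    )


def beam_search(M: ExpressionMatrix, params: SearchParams) -> SearchResult:
    """Breadth-first beam search over cell subsets.

    Level 2 evaluates all cell pairs; each later level extends the top
    ``beam_width`` frontier sets by one cell each.  Invalid candidates
    (no positive-gain gene) stay in the frontier with objective 0 — a
    superset may still be valid — but are never reported as solutions.
    Stops when the frontier is empty, the best frontier objective has
    not improved for ``patience`` consecutive levels, or the level
    exceeds ``max_cells``.  Fully deterministic.
    """
    if not M.normalized:
        raise ValueError("beam_search expects a normalized matrix")
    n_cells = M.n_cells
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    pre = _Precomp(M, params)

    best: Bicluster | None = None
    best_key: tuple[float, int] | None = None  # (objective, -|J|); lex by scan order
    levels: list[LevelLog] = []

    # frontier: list of (cells tuple, objective, stats triple)
    frontier = [
        ((c,), 0.0, (pre.values[:, c], pre.pos[:, c], pre.neg[:, c]))
        for c in range(n_cells)
    ]
    max_level = n_cells if params.max_cells is None else min(n_cells, params.max_cells)
    best_frontier_obj = -np.inf
    stall = 0
    level = 1

    while frontier and level < max_level:
        level += 1
        seen: set[tuple[int, ...]] = set()
        # child stats are parent stats + one column; store only the
        # (parent stats, added cell) recipe and rebuild for survivors,
        # so memory stays O(beam_width * |G|) per level
        children = []  # (cells, objective, gene_idx, parent_stats, added cell)
        for cells, _, stats in frontier:
            for c in range(n_cells):
                if c in cells:
                    continue
                child = tuple(sorted(cells + (c,)))
                if child in seen:
                    continue
                seen.add(child)
                genes, obj = pre.evaluate(
                    stats[0] + pre.values[:, c],
                    stats[1] + pre.pos[:, c],
                    stats[2] + pre.neg[:, c],
                    level,
                )
                children.append((child, obj if genes.size else 0.0, genes, stats, c))
        if not children:
            break

        children.sort(key=lambda e: e[0])  # lexicographic for tie stability
        level_best = -np.inf
        for cells, obj, genes, _, _ in children:
            level_best = max(level_best, obj)
            if genes.size and _within_bounds(level, params):
                key = (obj, -len(cells))
                if best_key is None or key > best_key:
                    best = _make_bicluster(M, genes, cells, obj)
                    best_key = key

        top = heapq.nlargest(
            params.beam_width, children, key=lambda e: (e[1], [-c for c in e[0]])
        )
        frontier = [
            (
                cells,
                obj,
                (
                    stats[0] + pre.values[:, c],
                    stats[1] + pre.pos[:, c],
                    stats[2] + pre.neg[:, c],
                ),
            )
            for cells, obj, genes, stats, c in top
        ]
        levels.append(LevelLog(level, len(children), len(frontier), level_best))

        if level_best > best_frontier_obj:
            best_frontier_obj = level_best
            stall = 0
        else:
            stall += 1
            if stall >= params.patience:
                break

    msg = "" if best is not None else (
        "no feasible bicluster: no cell subset admits a positive-gain gene "
        "set within the constraint"
    )
    return SearchResult(best, pre.n_evaluations, levels, msg)


def exhaustive_search(
    M: ExpressionMatrix,
    params: SearchParams,
    *,
    force: bool = False,
) -> SearchResult:
    """Enumerate every cell subset of admissible size — the exact oracle.

    Complexity O(|G| * 2^|C|); guarded to |C| <= 20 unless ``force``.
    Ties are broken toward smaller cell sets, then lexicographic cell
    order (combinations are generated in that order; first win stands).
    """
    if not M.normalized:
        raise ValueError("exhaustive_search expects a normalized matrix")
    n_cells = M.n_cells
    if n_cells > EXHAUSTIVE_CELL_GUARD and not force:
        raise ValueError(
            f"exhaustive search over {n_cells} cells exceeds the guard "
            f"({EXHAUSTIVE_CELL_GUARD}); pass force=True to override"
        )
    pre = _Precomp(M, params)
    max_size = n_cells if params.max_cells is None else min(n_cells, params.max_cells)

    best: Bicluster | None = None
    best_obj = 0.0
    for size in range(params.min_cells, max_size + 1):
        for cells in combinations(range(n_cells), size):
            genes, obj = pre.evaluate(*pre.stats_for(cells), size)
            if genes.size and obj > best_obj:
                best = _make_bicluster(M, genes, cells, obj)
                best_obj = obj
    msg = "" if best is not None else "no feasible bicluster in the full enumeration"
    return SearchResult(best, pre.n_evaluations, [], msg)


def top_k(
    M: ExpressionMatrix,
    params: SearchParams,
    k: int | None = None,
    *,
    solver=beam_search,
) -> list[Bicluster]:
    """Iterated extraction of up to k pairwise cell-disjoint biclusters.

    Solve, remove the solution's cells, re-apply the gene prevalence
    filter on the remaining cells (the follow-up search should see the
    same preconditions as the first), repeat.  Stops early when no
    solution remains or too few cells are left; shorter lists are legal.
    """
    k = params.top_k if k is None else k
    if k < 1:
        raise ValueError("k must be >= 1")
    results: list[Bicluster] = []
    current = M
    for _ in range(k):
        if current.n_cells < params.min_cells:
            break
        res = solver(current, params)
        if not res.found:
            break
        results.append(res.bicluster)
        drop = set(res.bicluster.cells)
        keep = [j for j, name in enumerate(current.cell_names) if name not in drop]
        if len(keep) < params.min_cells:
            break
        current = current.subset_cells(np.array(keep, dtype=int))
        try:
            current, _ = filter_genes(current, params.max_prevalence)
        except Exception:
            break
    return results
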