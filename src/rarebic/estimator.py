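"""Scikit-learn style estimator around the bicluster search.

`RareBiclusterMiner.fit` takes the sklearn orientation X of shape
(n_cells, n_genes): cells are samples, genes are features.  Internally
the matrix is transposed to the genes x cells orientation the search
operates on.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, BiclusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .core import SearchParams
from .matrix import ExpressionMatrix
from .preprocess import filter_genes, log_normalize
from .search import beam_search, exhaustive_search, top_k


class RareBiclusterMiner(BiclusterMixin, BaseEstimator):
    """Mine small, highly specific biclusters from expression data.

    Jointly selects a small set of cells and their marker genes by
    maximizing the penalized max-sum submatrix objective: the sum of the
    selected entries minus ``kappa`` times the out-of-cluster positive
    expression of the selected genes, subject to at most a ``mu``
    fraction of negative entries inside the bicluster.

    Parameters
    ----------
    n_biclusters : how many disjoint biclusters to extract iteratively.
    kappa : out-of-cluster penalty weight; None uses the default
        100 / n_cells.  Higher values return fewer, more specific genes.
    mu : allowed fraction of negative in-bicluster entries (default 0.1).
    max_prevalence : drop genes expressed in more than this fraction of
        cells before searching (default 0.25).
    normalize : 'auto' log-normalizes inputs that look like raw counts
        (all non-negative); True forces it; False expects a signed
        log-scale matrix.
    pseudo : pseudo-count of the log10(x + pseudo) transform.
    beam_width, min_cells, max_cells, patience : search controls.
    exact : use the exhaustive cell-subset enumeration (small data only).

    Attributes
    ----------
    rows_, columns_ : boolean arrays (n_biclusters_found, n) in the
        sklearn bicluster convention — rows are cells, columns genes.
    biclusters_found_ : list of Bicluster records (names, objective,
        negative fraction).
    labels_ : per-cell integer labels, -1 for unassigned cells.
    n_evaluations_ : candidate cell-set evaluations performed.

    Examples
    --------
    >>> from rarebic import toy_matrix, RareBiclusterMiner
    >>> X = toy_matrix().values.T   # cells x genes
    >>> est = RareBiclusterMiner(kappa=1, mu=0.1, max_prevalence=1.0,
    ...                          normalize=False).fit(X)
    >>> sorted(est.biclusters_found_[0].cells)
    ['c5', 'c6', 'c7']
    """

    def __init__(
        self,
        n_biclusters: int = 1,
        *,
        kappa: float | None = None,
        mu: float = 0.1,
        max_prevalence: float = 0.25,
        normalize: bool | str = "auto",
        pseudo: float = 0.1,
        beam_width: int = 100,
        min_cells: int = 2,
        max_cells: int | None = None,
        patience: int = 2,
        exact: bool = False,
    ):
        self.n_biclusters = n_biclusters
        self.kappa = kappa
        self.mu = mu
        self.max_prevalence = max_prevalence
        self.normalize = normalize
        self.pseudo = pseudo
        self.beam_width = beam_width
        self.min_cells = min_cells
        self.max_cells = max_cells
        self.patience = patience
        self.exact = exact

    def _params(self) -> SearchParams:
        return SearchParams(
            kappa=self.kappa,
            mu=self.mu,
            max_prevalence=self.max_prevalence,
            min_cells=self.min_cells,
            max_cells=self.max_cells,
            beam_width=self.beam_width,
            patience=self.patience,
            top_k=self.n_biclusters,
        )

    def fit(self, X, y=None, *, cell_names=None, gene_names=None):
        """Search X of shape (n_cells, n_genes) for rare biclusters."""
        X = check_array(X, ensure_all_finite=True, ensure_min_samples=2)
        n_cells, n_genes = X.shape
        self.n_features_in_ = n_genes
        M = ExpressionMatrix(
            X.T.copy(),
            gene_names=list(gene_names) if gene_names is not None else [],
            cell_names=list(cell_names) if cell_names is not None else [],
            normalized=bool(np.any(X < 0)),
        )
        do_norm = self.normalize if self.normalize != "auto" else not M.normalized
        if do_norm:
            M = log_normalize(M, self.pseudo)
        elif not M.normalized:
            M.normalized = True  # caller vouches the scale is signed-log
        if self.max_prevalence < 1:
            M, removed = filter_genes(M, self.max_prevalence)
            self.filtered_genes_ = removed
        else:
            self.filtered_genes_ = []

        params = self._params()

        def _solver(mat, p):
            if self.exact:
                return exhaustive_search(mat, p)
            return beam_search(mat, p)

        self._eval_count = 0

        def counting_solver(mat, p):
            res = _solver(mat, p)
            self._eval_count += res.n_evaluations
            return res

        found = top_k(M, params, self.n_biclusters, solver=counting_solver)
        self.biclusters_found_ = found
        self.n_evaluations_ = self._eval_count

        cell_lookup = {name: j for j, name in enumerate(M.cell_names)}
        rows = np.zeros((len(found), n_cells), dtype=bool)
        cols = np.zeros((len(found), n_genes), dtype=bool)
        # map (possibly filtered) gene names back to original feature indices
        original_names = (
            list(gene_names)
            if gene_names is not None
            else [f"g{i + 1}" for i in range(n_genes)]
        )
        gene_back = {name: i for i, name in enumerate(original_names)}
        self.labels_ = np.full(n_cells, -1, dtype=int)
        for b, bc in enumerate(found):
            for c in bc.cells:
                rows[b, cell_lookup[c]] = True
                self.labels_[cell_lookup[c]] = b
            for g in bc.genes:
                cols[b, gene_back[g]] = True
        self.rows_ = rows
        self.columns_ = cols
        self.objective_ = found[0].objective if found else None
        return self

    def fit_predict(self, X, y=None, **kwargs):
        """Fit and return per-cell labels (-1 = not in any bicluster)."""
        return self.fit(X, **kwargs).labels_
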