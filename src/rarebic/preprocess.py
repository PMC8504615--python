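"""Log-normalization and the gene prevalence filter.

The search assumes a signed matrix where positive means "expressed".  Raw
counts x are mapped through log10(x + pseudo); with the default
pseudo = 0.1 the raw expression threshold 0.9 lands exactly at zero, so
"expressed" on the normalized scale (entry > 0) is "raw count > 0.9".

Genes expressed in more than ``max_prevalence`` of the cells (default 25%)
are removed before the search: the goal is markers of small subpopulations,
not generic markers of ubiquitous expression, and ubiquitous genes would
drag the optimum toward large unspecific biclusters.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .matrix import ExpressionMatrix, MatrixError


def log_normalize(
    raw: ExpressionMatrix,
    pseudo: float = 0.1,
    *,
    expression_threshold: float | None = None,
    force: bool = False,
) -> ExpressionMatrix:
    """Map each raw count x to log10(x + pseudo).

    Parameters
    ----------
    raw
        Matrix of non-negative raw counts (``normalized`` False).
    pseudo
        Positive pseudo-count.  The implied raw "expressed" threshold is
        ``1 - pseudo`` (the count whose transform is exactly zero).
    expression_threshold
        Optional explicit raw threshold t: subtracts log10(t + pseudo) so
        that raw count t maps to zero.  Off by default.
    force
        Re-normalize even if the matrix is flagged normalized.

    Raises
    ------
    MatrixError
        On negative entries (naming the offending gene/cell) or if the
        matrix is already normalized and ``force`` is not set.
    ValueError
        On non-positive ``pseudo``.
    """
    if pseudo <= 0:
        raise ValueError(f"pseudo must be > 0, got {pseudo}")
    if raw.normalized and not force:
        raise MatrixError(
            "matrix is already normalized (contains signed values); "
            "re-normalizing would corrupt it — pass force=True to override"
        )
    if np.any(raw.values < 0):
        i, j = np.argwhere(raw.values < 0)[0]
        raise MatrixError(
            f"negative raw count at gene {raw.gene_names[i]!r}, "
            f"cell {raw.cell_names[j]!r}: input does not look like counts"
        )
    out = np.log10(raw.values + pseudo)
    if expression_threshold is not None:
        if expression_threshold < 0:
            raise ValueError("expression_threshold must be >= 0")
        out = out - np.log10(expression_threshold + pseudo)
    return replace(raw, values=out, normalized=True)


def filter_genes(
    M: ExpressionMatrix, max_prevalence: float = 0.25
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes expressed in more than ``max_prevalence`` of the cells.

    A gene is "expressed in cell j" iff its normalized entry is strictly
    positive.  The boundary is inclusive: a gene expressed in exactly
    ``max_prevalence`` of the cells is kept ("more than" is strict).

    Returns the filtered matrix (gene order preserved) and the names of
    the removed genes.
    """
    if not M.normalized:
        raise MatrixError("prevalence filter requires a normalized matrix")
    if not 0 < max_prevalence <= 1:
        raise ValueError(f"max_prevalence must be in (0, 1], got {max_prevalence}")
    prevalence = (M.values > 0).mean(axis=1)
    keep = prevalence <= max_prevalence
    if not keep.any():
        raise MatrixError(
            "every gene is expressed in more than "
            f"{max_prevalence:.0%} of cells; raise max_prevalence"
        )
    removed = [g for g, k in zip(M.gene_names, keep) if not k]
    return M.subset_genes(np.flatnonzero(keep)), removed


class LogNormalizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: counts -> signed log10(x + pseudo).

    Operates on arrays of shape (n_cells, n_genes), the sklearn
    samples-by-features orientation.
    """

    def __init__(self, pseudo: float = 0.1):
        self.pseudo = pseudo

    def fit(self, X, y=None):
        check_array(X, ensure_all_finite=True)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X, ensure_all_finite=True)
        if self.pseudo <= 0:
            raise ValueError(f"pseudo must be > 0, got {self.pseudo}")
        if np.any(X < 0):
            raise ValueError("negative entries: expected raw counts")
        return np.log10(X + self.pseudo)


class GenePrevalenceFilter(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer removing high-prevalence genes.

    Input is (n_cells, n_genes) normalized values; features whose
    expressed fraction strictly exceeds ``max_prevalence`` are dropped.
    """

    def __init__(self, max_prevalence: float = 0.25):
        self.max_prevalence = max_prevalence

    def fit(self, X, y=None):
        X = check_array(X, ensure_all_finite=True)
        if not 0 < self.max_prevalence <= 1:
            raise ValueError(
                f"max_prevalence must be in (0, 1], got {self.max_prevalence}"
            )
        prevalence = (X > 0).mean(axis=0)
        self.support_ = prevalence <= self.max_prevalence
        self.n_features_in_ = X.shape[1]
        if not self.support_.any():
            raise ValueError(
                "every gene exceeds the prevalence threshold; raise max_prevalence"
            )
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X, ensure_all_finite=True)
        return X[:, self.support_]

    def get_support(self, indices: bool = False):
        check_is_fitted(self)
        return np.flatnonzero(self.support_) if indices else self.support_
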