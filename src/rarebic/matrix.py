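"""Expression matrix container.

The canonical in-memory orientation is genes as rows, cells as columns
(M in R^{|G| x |C|}).  After log-normalization a positive entry means the
gene is expressed in that cell; a non-positive entry means negligibly
expressed or not at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class MatrixError(ValueError):
    """Invalid expression-matrix input."""


@dataclass
class ExpressionMatrix:
    """A genes x cells grid of expression values with row/column names.

    Parameters
    ----------
    values
        2-D float array, shape ``(n_genes, n_cells)``.  Raw counts are
        finite and non-negative; normalized values are finite and signed.
    gene_names, cell_names
        Unique identifiers for rows and columns.
    normalized
        True once values are on the signed log scale.
    """

    values: np.ndarray
    gene_names: list[str] = field(default_factory=list)
    cell_names: list[str] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixError(f"values must be 2-D, got shape {self.values.shape}")
        n_genes, n_cells = self.values.shape
        if not self.gene_names:
            self.gene_names = [f"g{i + 1}" for i in range(n_genes)]
        if not self.cell_names:
            self.cell_names = [f"c{j + 1}" for j in range(n_cells)]
        self.gene_names = [str(g) for g in self.gene_names]
        self.cell_names = [str(c) for c in self.cell_names]
        if len(self.gene_names) != n_genes:
            raise MatrixError(
                f"{len(self.gene_names)} gene names for {n_genes} rows"
            )
        if len(self.cell_names) != n_cells:
            raise MatrixError(
                f"{len(self.cell_names)} cell names for {n_cells} columns"
            )
        for axis, names in (("gene", self.gene_names), ("cell", self.cell_names)):
            if len(set(names)) != len(names):
                seen: set[str] = set()
                dup = next(n for n in names if n in seen or seen.add(n))
                raise MatrixError(f"duplicate {axis} name: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise MatrixError(
                f"non-finite entry at gene {self.gene_names[i]!r}, "
                f"cell {self.cell_names[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, name: str) -> int:
        try:
            return self.gene_names.index(name)
        except ValueError:
            raise KeyError(f"unknown gene {name!r}") from None

    def cell_index(self, name: str) -> int:
        try:
            return self.cell_names.index(name)
        except ValueError:
            raise KeyError(f"unknown cell {name!r}") from None

    def cell_indices(self, names) -> np.ndarray:
        return np.array([self.cell_index(n) for n in names], dtype=int)

    def subset_cells(self, keep: np.ndarray) -> "ExpressionMatrix":
        """New matrix restricted to the cell columns in ``keep`` (indices)."""
        keep = np.asarray(keep, dtype=int)
        return replace(
            self,
            values=self.values[:, keep].copy(),
            cell_names=[self.cell_names[j] for j in keep],
        )

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep, dtype=int)
        return replace(
            self,
            values=self.values[keep, :].copy(),
            gene_names=[self.gene_names[i] for i in keep],
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        state = "normalized" if self.normalized else "raw"
        return (
            f"ExpressionMatrix({self.n_genes} genes x {self.n_cells} cells, "
            f"{state})"
        )
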