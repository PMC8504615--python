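import numpy as np
import pytest

from rarebic import ExpressionMatrix, toy_matrix


@pytest.fixture
def toy():
    return toy_matrix()


@pytest.fixture
def random_signed_matrix():
    """Factory for small mixed-sign normalized matrices."""

    def make(seed: int, n_genes: int = 15, n_cells: int = 8) -> ExpressionMatrix:
        rng = np.random.default_rng(seed)
        sparsify = rng.choice([0.3, 1.0], size=(n_genes, n_cells))
        vals = np.round(rng.uniform(-2, 3, size=(n_genes, n_cells)) * sparsify, 2)
        return ExpressionMatrix(vals, normalized=True)

    return make


@pytest.fixture
def raw_counts_matrix():
    def make(seed: int, n_genes: int = 20, n_cells: int = 10) -> ExpressionMatrix:
        rng = np.random.default_rng(seed)
        vals = rng.poisson(2.0, size=(n_genes, n_cells)).astype(float)
        return ExpressionMatrix(vals)

    return make
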