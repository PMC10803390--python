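import numpy as np
import pytest
import scipy.sparse as sp

from retinalight import GeneExpressionMatrix, SyntheticConfig, generate_counts


def make_gem(counts, genes=None, barcodes=None, condition=None):
    """Build a GeneExpressionMatrix from a dense array."""
    counts = np.asarray(counts)
    n, g = counts.shape
    return GeneExpressionMatrix(
        barcodes=barcodes or [f"BC{i:04d}" for i in range(n)],
        genes=genes or [f"G{j:04d}" for j in range(g)],
        counts=sp.csr_matrix(counts),
        condition=condition,
    )


def random_gem(rng, n_cells=20, n_genes=30, density=0.3, max_count=20, n_mito=3):
    """Random sparse integer matrix with a few mt- genes."""
    dense = rng.integers(1, max_count + 1, size=(n_cells, n_genes))
    dense *= rng.random((n_cells, n_genes)) < density
    n_mito = min(n_mito, n_genes)
    genes = [f"mt-G{j}" for j in range(n_mito)] + [
        f"G{j:04d}" for j in range(n_genes - n_mito)
    ]
    return make_gem(dense, genes=genes)


@pytest.fixture(scope="session")
def default_dataset():
    """Full study-design synthetic dataset (defaults, seed 1): the two
    matrices and their ground truth. Generated once per session."""
    return generate_counts(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced two-condition dataset for cheap end-to-end tests."""
    cfg = SyntheticConfig(n_cells_dark=1200, n_cells_light=1200, seed=11)
    return cfg, generate_counts(cfg)
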