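import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

from gdtx import CountMatrix, SimDesign, simulate_counts

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_count_matrix(rng, n_genes=20, n_cells=50, density=0.3,
                        mito_genes=2) -> CountMatrix:
    """Small random sparse count matrix with a mitochondrial gene block."""
    mat = (rng.random((n_genes, n_cells)) < density) * rng.integers(
        1, 20, size=(n_genes, n_cells)
    )
    genes = [f"G{i}" for i in range(n_genes - mito_genes)] + [
        f"MT-{i}" for i in range(mito_genes)
    ]
    barcodes = [f"BC{i}" for i in range(n_cells)]
    return CountMatrix(genes, barcodes, sp.csr_matrix(mat))


@pytest.fixture(scope="session")
def sim_default():
    """One default planted-cluster simulation shared across tests."""
    return simulate_counts(SimDesign(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
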