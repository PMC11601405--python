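import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import traitblocks as tb

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_binary_matrix(rng: np.random.Generator, n: int, m: int, density: float):
    """Random bit-packed matrix with labelled axes for testing."""
    dense = rng.random((n, m)) < density
    return tb.BinaryMatrix.from_dense(
        dense,
        trait_ids=[f"t{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(m)],
        threshold_used=0.5,
    )


@pytest.fixture
def small_matrix():
    """The 4-row worked matrix whose biclusters are known by hand."""
    dense = np.array(
        [
            [1, 1, 1, 0, 0],
            [1, 1, 1, 0, 1],
            [0, 1, 1, 1, 0],
            [1, 1, 0, 0, 0],
        ],
        dtype=bool,
    )
    return tb.BinaryMatrix.from_dense(
        dense, [f"t{i}" for i in range(4)], list("abcde"), 0.5
    )


@pytest.fixture
def clean_planted():
    """Noise-free dataset with three disjoint planted blocks."""
    return tb.generate_planted_dataset(
        n_traits=30,
        n_genes=120,
        blocks=[(4, 12), (4, 12), (4, 12)],
        signal_p_max=1e-12,
        background_sig_rate=0.0,
        seed=11,
        n_noise_terms=10,
        term_size=12,
    )
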