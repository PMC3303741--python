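import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trinet import ExpressionMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix(rng):
    """3 genes x 4 samples of independent noise."""
    return ExpressionMatrix(
        ["geneA", "geneB", "geneC"],
        rng.normal(size=(3, 4)),
        ["s1", "s2", "s3", "s4"],
    )


def make_chain_data(betas, noise_sd, n_samples, seed, gene_names=None):
    """Simulate a linear chain g1 -> g2 -> ... with the given coefficients."""
    rng = np.random.default_rng(seed)
    n = len(betas) + 1
    genes = gene_names or [f"g{i + 1}" for i in range(n)]
    x = np.zeros((n, n_samples))
    x[0] = rng.normal(0, 1, n_samples)
    for i, b in enumerate(betas, start=1):
        x[i] = b * x[i - 1] + rng.normal(0, noise_sd, n_samples)
    return ExpressionMatrix(genes, x, [f"s{j}" for j in range(n_samples)])
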