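import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def block_expression():
    """Two planted coexpression blocks (rho=0.9) plus noise genes."""
    from radiogenomap import simulate_expression

    expr, truth = simulate_expression(
        n_genes=70, n_samples=200, n_blocks=2, block_size=25, rho=0.9, seed=7
    )
    return expr, truth


@pytest.fixture
def small_features():
    """A tiny semantic feature table: one binary, one ordinal, one rare binary."""
    from radiogenomap import SemanticFeatureTable

    rng = np.random.default_rng(3)
    n = 100
    data = pd.DataFrame(
        {
            "solid": rng.integers(0, 2, n).astype(float),
            "margin": rng.integers(0, 5, n).astype(float),
            "rare": (rng.random(n) < 0.05).astype(float),
        },
        index=[f"p{i:03d}" for i in range(n)],
    )
    book = {
        "solid": {"type": "binary", "levels": None},
        "margin": {"type": "ordinal",
                   "levels": ["smooth", "lobulated", "irregular", "spiculated", "poorly-defined"]},
        "rare": {"type": "binary", "levels": None},
    }
    return SemanticFeatureTable(data=data, codebook=book)
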