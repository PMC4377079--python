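import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrsummary import IndividualData, SummarySet, summary_set_from_arrays

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231)


@pytest.fixture
def five_variant_set() -> SummarySet:
    """A well-behaved synthetic summary set with a common underlying slope ~0.3."""
    return summary_set_from_arrays(
        beta_x=[0.10, 0.22, 0.15, 0.30, 0.08],
        se_x=[0.010, 0.020, 0.015, 0.020, 0.010],
        beta_y=[0.032, 0.070, 0.048, 0.095, 0.024],
        se_y=[0.012, 0.020, 0.016, 0.025, 0.011],
    )


@pytest.fixture
def small_individual(rng) -> IndividualData:
    """n=800, K=3 dataset with strong instruments and mild confounding."""
    n = 800
    g = rng.binomial(2, 0.3, size=(n, 3)).astype(float)
    u = rng.standard_normal(n)
    x = g @ [0.5, 0.4, 0.6] + u + rng.standard_normal(n)
    y = 0.2 * x - u + rng.standard_normal(n)
    return IndividualData(genotypes=g, x=x, y=y, u=u)
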