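import numpy as np
import pytest

from fieldgap import SyntheticConfig, generate_landscape


def small_config(**overrides) -> SyntheticConfig:
    """A fast landscape: 40 fields, 3 years, 64x80 pixels."""
    base = dict(n_fields=40, n_years=3, grid_shape=(64, 80), seed=11)
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_landscape():
    """Rendered small landscape shared by read-only tests."""
    return generate_landscape(small_config())


@pytest.fixture(scope="session")
def small_truth(small_landscape):
    return small_landscape[3]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
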