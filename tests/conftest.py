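import numpy as np
import pytest

from amrsid import PhantomSpec, RegionSample, generate_phantom


def make_sample(values, positions=None, weights=None, region="IVD"):
    """Small RegionSample helper for unit tests."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if positions is None:
        positions = np.column_stack([np.arange(n), np.zeros(n), np.zeros(n)])
    if weights is None:
        weights = np.full(n, 1.0 / n)
    return RegionSample(
        positions=positions, intensities=values, weights=weights, region_name=region
    )


@pytest.fixture(scope="session")
def default_phantom():
    """One default phantom pair, shared across read-only tests."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def small_spec():
    """Reduced-grid phantom spec for tests that generate many volumes."""
    return PhantomSpec(
        grid_shape=(32, 32, 16),
        ivd_semi_axes=(10.0, 8.0, 4.0),
        seed=0,
    )
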