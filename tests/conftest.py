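import numpy as np
import pytest

from ventjac import DisplacementField, GridDomain


@pytest.fixture
def domain8():
    return GridDomain((8, 8, 8))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def smooth_field8(domain8, rng):
    """A seeded smooth random field on an 8^3 grid (diffeomorphic amplitudes)."""
    from scipy.ndimage import gaussian_filter

    data = np.stack(
        [gaussian_filter(rng.standard_normal(domain8.shape), 1.5, mode="nearest") for _ in range(3)]
    )
    data *= 0.5 / np.abs(data).max()
    return DisplacementField(domain8, data)
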