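import numpy as np
import pytest

from bandelet import TransformParams, build_dictionary


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dictionary():
    """Compact flow dictionary used where search breadth is not the point."""
    return build_dictionary(n_directions=4, max_slope=2.0)


@pytest.fixture
def default_dictionary():
    return build_dictionary(n_directions=16, max_slope=2.0)


@pytest.fixture
def fast_params():
    """Transform parameters scaled for quick unit tests."""
    return TransformParams(levels=1, T=30.0, lam=4.0, n_directions=4, min_block=4)


def make_step_edge(size: int, slope: float, offset: float = 0.0,
                   lo: float = 20.0, hi: float = 120.0) -> np.ndarray:
    """Noise-free straight edge: bright where x2 - slope*x1 < centre + offset."""
    x1, x2 = np.mgrid[0:size, 0:size]
    centre = size / 2 - slope * size / 2
    return np.where(x2 - slope * x1 < centre + offset, hi, lo).astype(float)
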