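import numpy as np
import pytest

from nanotex import HeightMap, SceneSpec, generate_fbm_surface


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_map(rng):
    """512x512 i.i.d. Gaussian surface, mu=50 nm, sigma=10 nm."""
    return HeightMap(rng.normal(50.0, 10.0, (512, 512)), 4.0, 4.0, label="gaussian")


@pytest.fixture
def small_fbm():
    """Deterministic 128x128 self-affine surface (H=0.5, Rq=10 nm)."""
    return generate_fbm_surface(SceneSpec(size_px=128, hurst=0.5, rms_target=10.0, seed=7))


def random_heightmap(rng, rows=None, cols=None, nonneg=True):
    """Random test map with AFM-like scale (heights in [0, ~200] nm)."""
    rows = rows or int(rng.integers(2, 33))
    cols = cols or int(rng.integers(2, 33))
    z = rng.normal(100.0, 30.0, (rows, cols))
    if nonneg:
        z -= min(z.min(), 0.0)
    return HeightMap(z, 4.0, 4.0)
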