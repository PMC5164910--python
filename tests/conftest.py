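import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from gafcm import FCMParams, GAParams, PhantomSpec, PipelineConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_block_image():
    """Two well-separated constant blocks: gray 20 and gray 230."""
    img = np.empty((4, 4))
    img[:, :2] = 20.0
    img[:, 2:] = 230.0
    return img


@pytest.fixture
def small_phantom():
    """64x64 phantom, moderate noise — fast enough for GA runs in tests."""
    spec = PhantomSpec(height=64, width=64, n_branches=5, width_range=(2.5, 3.5), noise_sigma=8.0)
    return generate(spec, np.random.default_rng(11))


@pytest.fixture
def fast_config():
    """Reduced-size pipeline configuration for quick end-to-end runs."""
    return PipelineConfig(
        fcm=FCMParams(n_clusters=4, max_iter=40),
        ga=GAParams(pop_size=20, chrom_len=4, generations=6),
        k_brightest=2,
    )


def random_instance(rng, max_pixels=16, max_clusters=4, min_clusters=1):
    """A random tiny image / center-vector pair for oracle comparisons."""
    n = int(rng.integers(1, max_pixels + 1))
    c = int(rng.integers(min_clusters, max_clusters + 1))
    x = rng.uniform(0.0, 255.0, size=n)
    centers = rng.uniform(0.0, 255.0, size=c)
    m = float(rng.uniform(1.3, 3.5))
    return x, centers, m
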