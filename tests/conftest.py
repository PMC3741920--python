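import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import ductmorph as dm


@pytest.fixture(scope="session")
def smooth_phantom():
    """Convex (lobe-free, noise-free) duct phantom with truth."""
    cfg = dm.PhantomConfig(
        image_size=(512, 512), lumen_radius=160, n_lobes=0,
        boundary_noise_amp=0.0, n_epithelial=24, n_stromal=12,
        cytoplasm_offset_mean=8.0, rng_seed=11,
    )
    image, truth = dm.generate_duct_phantom(cfg)
    return cfg, image, truth


@pytest.fixture(scope="session")
def papillary_phantom():
    """Three-frond papillary phantom with truth."""
    cfg = dm.PhantomConfig(n_lobes=3, lobe_area=2000.0, rng_seed=7)
    image, truth = dm.generate_duct_phantom(cfg)
    return cfg, image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_signature(rng, n=50, scale=10.0):
    """A random (L, A) signature with non-decreasing L."""
    L = np.cumsum(rng.uniform(0.2, 2.0, size=n))
    L -= L[0]
    A = rng.normal(0, scale, size=n)
    return dm.AtypiaSignature(L=L, A=A)
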