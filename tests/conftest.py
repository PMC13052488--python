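import numpy as np
import pytest

from oximc import (ChromophoreLibrary, MCConfig, OpticalSlab, ProbeGeometry,
                   SkinStack)


@pytest.fixture(scope="session")
def lib():
    return ChromophoreLibrary.default()


@pytest.fixture(scope="session")
def stack(lib):
    return SkinStack.default(lib)


@pytest.fixture(scope="session")
def probe():
    return ProbeGeometry()


@pytest.fixture
def single_layer_matched():
    """Absorbing-only slab with matched refractive indices (Beer-Lambert)."""
    return OpticalSlab(mu_a=np.array([1.0]), mu_s=np.array([0.0]),
                       g=np.array([0.0]), n=np.array([1.0]),
                       thickness=np.array([1.0]))


@pytest.fixture
def scattering_slab():
    """Single scattering+absorbing layer, matched indices."""
    return OpticalSlab(mu_a=np.array([0.05]), mu_s=np.array([10.0]),
                       g=np.array([0.8]), n=np.array([1.0]),
                       thickness=np.array([5.0]))


def small_cfg(seed=0, n=20000):
    return MCConfig(n_photons=n, rng_seed=seed)
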