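import numpy as np
import pytest

import landes
from landes import landuse_ca as ca


@pytest.fixture(scope="session")
def bundle60():
    """Small synthetic study area shared by fast tests."""
    return landes.generate_bundle((60, 60), seed=3)


@pytest.fixture(scope="session")
def bundle100():
    """Full-size synthetic study area for CA recovery tests."""
    return landes.generate_bundle((100, 100), seed=7)


@pytest.fixture(scope="session")
def drivers100(bundle100):
    return [getattr(bundle100, n) for n in bundle100.driver_names()]


@pytest.fixture(scope="session")
def model100(bundle100, drivers100):
    X, y = ca.sample_training(bundle100.landuse_t0, drivers100, n=2000,
                              seed=1, strategy="stratified")
    return ca.fit_suitability(X, y, seed=2)


@pytest.fixture(scope="session")
def suitability100(bundle100, drivers100, model100):
    return ca.suitability_surfaces(model100, bundle100.landuse_t0, drivers100)


def make_lu(values, **kw):
    """Helper: LandUseMap from a plain nested list."""
    return landes.LandUseMap(np.asarray(values, dtype=np.int16), **kw)
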