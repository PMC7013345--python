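import pytest

from pdtmon.layered_mc import (
    OpticalLayer,
    TissueModel,
    TransportConfig,
    default_rabbit_ear_model,
    simulate_transport,
)


@pytest.fixture(scope="session")
def ear405():
    return default_rabbit_ear_model(405)


@pytest.fixture(scope="session")
def ear660():
    return default_rabbit_ear_model(660)


@pytest.fixture(scope="session")
def result405_1m(ear405):
    """High-statistics transport through the ear model at 405 nm."""
    return simulate_transport(ear405, TransportConfig(seed=11, n_photons=1_000_000))


@pytest.fixture(scope="session")
def result660_1m(ear660):
    """High-statistics transport through the ear model at 660 nm."""
    return simulate_transport(ear660, TransportConfig(seed=12, n_photons=1_000_000))


@pytest.fixture(scope="session")
def beer_lambert_result():
    """Pure absorber (mua = 1/mm, no scattering, matched indices): the
    absorbed-dose profile has the closed form mua * exp(-mua z)."""
    slab = TissueModel((OpticalLayer("absorber", 3.0, 1.0, 1.0, 0.0),))
    return simulate_transport(slab, TransportConfig(seed=5, n_photons=1_000_000))
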