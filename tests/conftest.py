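import pytest

from pleioflux import (
    build_reference,
    extract_biomass_components,
    make_toy1,
    make_toy2,
)


@pytest.fixture(scope="session")
def toy1():
    return make_toy1()


@pytest.fixture(scope="session")
def toy2():
    return make_toy2()


@pytest.fixture(scope="session")
def toy1_ref(toy1):
    return build_reference(toy1, extract_biomass_components(toy1))


@pytest.fixture(scope="session")
def toy2_ref(toy2):
    return build_reference(toy2, extract_biomass_components(toy2))
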