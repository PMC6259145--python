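import numpy as np
import pytest

from saforge.nuclear_data import NeutronField, load_fixture


@pytest.fixture(scope="session")
def lu_fixture():
    return load_fixture("lu176_enriched")


@pytest.fixture(scope="session")
def yb_fixture():
    return load_fixture("yb176_enriched")


@pytest.fixture(scope="session")
def lu_natural_fixture():
    return load_fixture("lu_natural")


@pytest.fixture(scope="session")
def field_25():
    """2.5e14 thermal flux, f_H = 0.02 (direct-route reference field)."""
    return NeutronField(2.5e14, R_epi=0.02)


@pytest.fixture(scope="session")
def field_5e13():
    """5e13 thermal flux (indirect-route reference field)."""
    return NeutronField(5.0e13, R_epi=0.02)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
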