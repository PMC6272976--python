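import pytest

import fermkin as fk


@pytest.fixture(scope="session")
def pb_table() -> fk.DesignTable:
    """Packaged 12-run Plackett-Burman screening table."""
    return fk.load_pb_fixture()


@pytest.fixture(scope="session")
def bbd_table() -> fk.DesignTable:
    """Packaged 29-run Box-Behnken response-surface table."""
    return fk.load_bbd_fixture()


@pytest.fixture(scope="session")
def ea_fit(bbd_table) -> fk.QuadraticFit:
    """Quadratic enzyme-activity fit on the packaged design."""
    return fk.fit_quadratic(bbd_table, "EA")


@pytest.fixture(scope="session")
def bm_fit(bbd_table) -> fk.QuadraticFit:
    """Quadratic biomass fit on the packaged design."""
    return fk.fit_quadratic(bbd_table, "BM")


@pytest.fixture(scope="session")
def kinetic_params():
    """Fitted kinetic parameters for the nine operating conditions."""
    return fk.load_kinetic_params_fixture()
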