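import pytest

from colefit import ColeParams, FrequencyGrid, Z2Params, spectrum


@pytest.fixture(scope="session")
def default_grid() -> FrequencyGrid:
    return FrequencyGrid.default()


@pytest.fixture(scope="session")
def cole_params() -> ColeParams:
    return ColeParams(r0=100.0, rinf=50.0, cm=100e-9, alpha=0.85, td=0.0)


@pytest.fixture(scope="session")
def z2_params() -> Z2Params:
    return Z2Params(r0=100.0, rinf=50.0, cm_lf=100e-9, a=5e-14, alpha=0.85, td=0.0)


@pytest.fixture(scope="session")
def cole_spectrum(cole_params, default_grid):
    return spectrum(cole_params, default_grid)
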