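import matplotlib
import pytest

matplotlib.use("Agg")

from p4psim.params import ModelParams, P4PParams, RateParams, load_base_params


@pytest.fixture(scope="session")
def base_params() -> ModelParams:
    """The frozen calibrated parameter file shipped with the package."""
    return load_base_params()


@pytest.fixture
def null_rates() -> RateParams:
    return RateParams(r_revenue=0.0, r_conversion=0.0, r_depletion=0.0,
                      r_volume=0.0, r_attrition=0.0)


@pytest.fixture
def p4p_off() -> P4PParams:
    return P4PParams(enabled=False)
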