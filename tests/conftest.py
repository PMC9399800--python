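import numpy as np
import pytest

from sesakin import (
    ArrheniusParams,
    KineticParameters,
    ReactionConditions,
    VantHoffParams,
    reference_parameters,
)


@pytest.fixture(scope="session")
def ref_params() -> KineticParameters:
    """Reference parameter set used to generate all synthetic studies."""
    return reference_parameters()


@pytest.fixture(scope="session")
def perturbed_init(ref_params) -> KineticParameters:
    """Reference parameters perturbed +20%, the standard fit starting point."""
    return KineticParameters(
        arrhenius=ArrheniusParams(9.74 * 1.2, 21.4 * 1.2),
        vant_hoff=VantHoffParams(0.536 * 1.2, 34578.0 * 1.2),
        K1=4029.99,
    )


@pytest.fixture
def simple_conditions() -> ReactionConditions:
    """A single 80 degC run at the design-centre conditions."""
    return ReactionConditions(T=353.15, w_cat=0.016, C_A0=21.47,
                              run_id="centre")


def pytest_configure(config):
    np.seterr(all="warn")
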