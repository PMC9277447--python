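import numpy as np
import pytest

from tcaflux import FluxParameters, TracerSpec, build_tca_network


@pytest.fixture(scope="session")
def network():
    return build_tca_network("full")


@pytest.fixture(scope="session")
def tracer():
    return TracerSpec()


@pytest.fixture(scope="session")
def mixed_fluxes():
    """The mixed-flux reference case exercising every pathway."""
    return FluxParameters(f_pdh=0.6, y_pc=0.2, pk=0.1, y_s=0.1)


@pytest.fixture(scope="session")
def mixed_state(network, mixed_fluxes, tracer):
    return network.steady_state(mixed_fluxes, tracer)


def random_admissible_fluxes(rng: np.random.Generator) -> FluxParameters:
    """Draw a flux vector satisfying all admissibility constraints."""
    f_pdh = rng.uniform(0.2, 1.0)
    y_pc = rng.uniform(0.0, 0.5)
    y_s = rng.uniform(0.0, 0.5)
    pk = rng.uniform(0.0, 1.0) * (y_pc + y_s)
    return FluxParameters(f_pdh=f_pdh, y_pc=y_pc, pk=pk, y_s=y_s)
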