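import numpy as np
import pytest

from indentmech import (NoiseSpec, ProtocolSpec, SLSParams, SpecimenGeometry,
                        generate_sls_curve)


@pytest.fixture(scope="session")
def geometry():
    # alpha = 1 specimen with the study's indenter radius and nu
    return SpecimenGeometry(thickness_um=525.0)


@pytest.fixture(scope="session")
def protocol():
    return ProtocolSpec()


@pytest.fixture(scope="session")
def sls_params(geometry):
    return SLSParams(e_inf_mpa=0.5, e_0_mpa=1.5, tau_s=1.0, geometry=geometry)


@pytest.fixture(scope="session")
def clean_curve(sls_params, protocol):
    """Noise-free SLS curve at 100 Hz with its ground truth."""
    return generate_sls_curve(sls_params, protocol, rate_hz=100.0)


@pytest.fixture(scope="session")
def noisy_curve(sls_params, protocol):
    """Same protocol with 0.2 um displacement noise and small load noise."""
    noise = NoiseSpec(load_sigma_n=0.002, displacement_sigma_um=0.2, seed=42)
    return generate_sls_curve(sls_params, protocol, rate_hz=100.0, noise=noise)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
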