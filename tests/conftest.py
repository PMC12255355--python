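import numpy as np
import pytest

import pafluence as pf


@pytest.fixture(scope="session")
def muscle700():
    return pf.tissue_properties("muscle", 700)


@pytest.fixture(scope="session")
def scattering_medium():
    """Reference medium with scattering-to-absorption ratio 100:1."""
    return pf.reference_medium("mus_mua_100")


@pytest.fixture(scope="session")
def absorbing_medium():
    """Reference medium with scattering-to-absorption ratio 1:1000."""
    return pf.reference_medium("mus_mua_0.001")


def power_law_profile(beta, mu, r=None, scale=1.0):
    """Noiseless phi = scale * r**(-beta) * exp(-mu*r) on a fine grid."""
    if r is None:
        r = np.arange(0.05, 15.0, 0.1)
    return pf.FluenceProfile(r=r, phi=scale * r ** (-beta) * np.exp(-mu * r))


@pytest.fixture(scope="session")
def warm_mc():
    """Compile the transport kernel once so per-test timings are honest."""
    vol = pf.homogeneous_volume(6.0, 0.6, pf.reference_medium("mus_mua_100"))
    src = pf.SourceSpec(kind="isotropic_point")
    pf.run_mc(vol, src, photons=1000, seed=0)
    return True
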