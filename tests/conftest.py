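import numpy as np
import pytest

from bbbleak import (AcquisitionProtocol, extract_vif, fit_patlak_map,
                     tissue_concentration)
from bbbleak.simulate import PhantomSpec, simulate_subject


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def noiseless_subject():
    """Default phantom with zero noise (exact-recovery surface)."""
    return simulate_subject(PhantomSpec(noise_sigma_rel=0.0))


@pytest.fixture(scope="session")
def noiseless_products(noiseless_subject):
    """(vif, concentration, leakage map) of the noiseless phantom."""
    s = noiseless_subject
    vif = extract_vif(s.fast, s.sinus_mask, s.calibration,
                      slow_series=s.slow, hematocrit=s.hematocrit)
    conc = tissue_concentration(s.fast, s.slow, s.t10_ms,
                                s.protocol.r1_relaxivity, s.brain_mask,
                                s.protocol.td_ms)
    lmap = fit_patlak_map(conc, vif, s.brain_mask)
    return vif, conc, lmap


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
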