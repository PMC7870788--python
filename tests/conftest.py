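import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lipidpore as lp

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def patch_energetics() -> lp.PoreEnergetics:
    """Rectified-patch fixture of the recovery studies."""
    return lp.PoreEnergetics(dmu0_kT=4.0, alpha_kT_per_V2=40.0, offset_V=0.2)


@pytest.fixture
def blm_energetics() -> lp.PoreEnergetics:
    """Flat-membrane fixture: no offset, pores open symmetrically at high |V|."""
    return lp.PoreEnergetics(dmu0_kT=4.0, alpha_kT_per_V2=-100.0, offset_V=0.0)


@pytest.fixture
def env() -> lp.Environment:
    return lp.Environment()


@pytest.fixture
def protocol() -> lp.VoltageProtocol:
    return lp.build_protocol()


def make_equilibrium_series(cs, pe, env, seed, noise_sd_A=2e-12,
                            protocol=None) -> list:
    """17-level series from the ensemble-mean conduction model plus white noise."""
    protocol = protocol or lp.build_protocol()
    nm = lp.NoiseModel(current_noise_sd_A=noise_sd_A)
    return lp.simulate_trace(protocol, cs, pe, env, nm=nm, seed=seed,
                             gating="equilibrium")
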