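import pytest
from hypothesis import HealthCheck, settings

from synapse_sim import (BindingConstants, RunConfig, derive_2d_constants,
                         run_invivo)
from synapse_sim.config import InVivoSettings

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def binding_default() -> BindingConstants:
    """Blinatumomab-like arm kinetics: KD_CD3 = 2.6e-7 M, KD_CD19 = 1.5e-9 M."""
    return BindingConstants(kon_A=1e4, koff_A=2.6e-3, kon_B=1e4, koff_B=1.5e-5)


@pytest.fixture(scope="session")
def k2d_default(binding_default):
    return derive_2d_constants(binding_default, 20.0)


@pytest.fixture(scope="session")
def invivo_result_small():
    """One shared short in vivo run (3 replicates, 3 days, reduced agent
    count) reused by the organ-level assertions."""
    cfg = RunConfig(model="invivo", replicates=3, seed=11,
                    invivo=InVivoSettings(duration_days=3.0, agent_cap=1500))
    return run_invivo(cfg)
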