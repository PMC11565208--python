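import pytest

from c4wue.c4_model import C4Params
from c4wue.synthdata import GenotypeEffect, SimConfig, sim_aci_curve


@pytest.fixture
def base_params() -> C4Params:
    """Wild-type-like C4 biochemistry used across the suite."""
    return C4Params(vpmax=120.0, vmax=45.0, kp=80.0, rd=2.0)


@pytest.fixture
def noiseless_curve(base_params):
    """A noise-free A/ci curve at the 11 cuvette CO2 protocol steps."""
    cfg = SimConfig(seed=0, noise_cv_a=0.0, noise_cv_gs=0.0)
    return sim_aci_curve(GenotypeEffect(name="WT"), base_params, cfg)
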