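import pytest
from hypothesis import settings as hyp_settings

from pre2restraints.pre_extraction import AcquisitionSettings
from pre2restraints.sbmf import SBMFParameters
from pre2restraints.synthetic import attach_tag, make_toy_complex

hyp_settings.register_profile("default", derandomize=True, max_examples=50)
hyp_settings.load_profile("default")


@pytest.fixture(scope="session")
def acquisition():
    """Methyl-HMQC acquisition settings used throughout the tests."""
    return AcquisitionSettings(
        field_mhz=850.0, delta_total=7.7e-3, delay_a=0.0, delay_b=10e-3,
        lb_f1=15.0, lb_f2=15.0, r2_dia_h=25.0, r2_dia_mq=30.0,
    )


@pytest.fixture(scope="session")
def sbmf_params():
    """Restraint-generation defaults: S^2 = 1, tau1 = 20 ns, 850 MHz."""
    return SBMFParameters(tau_1=20e-9, s2=1.0, field_mhz=850.0)


@pytest.fixture()
def toy_truth():
    """Contact-pose two-helix complex with two tags on chain A."""
    truth = make_toy_complex(n_residues_a=30, n_residues_b=30, seed=11)
    attach_tag(truth, "A", 5)
    attach_tag(truth, "A", 15)
    return truth
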