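import pytest

from ifflpulse import (
    HybridParams,
    InducerCondition,
    RNAOnlyParams,
)


@pytest.fixture
def unit_rna_params():
    """All-ones RNA-only parameter set used by the hand-arithmetic oracles."""
    return RNAOnlyParams(
        alpha_X=1, alpha_Y=1, alpha_Z=1, alpha_GFP=1, gamma=1, omega=1,
        delta_X=1, delta_Y=1, delta_Z=1, delta_GFP=1,
        K_ara=1, K_IPTG=1, m=1, n=1, S_G=1)


@pytest.fixture
def unit_hybrid_params():
    """All-ones hybrid parameter set for the hand-arithmetic oracle."""
    return HybridParams(
        alpha_X=1, alpha_Y=1, alpha_Z=1, alpha_T=1, alpha_G=1,
        gamma=1, omega=1,
        delta_X=1, delta_Y=1, delta_Z=1, delta_CY=1, delta_CZ=1,
        delta_T=1, delta_G=1, K_IPTG=1, n=1, k_atc=1, k_off=1, S_G=1)


@pytest.fixture
def both_inducers():
    return InducerCondition(iptg=1.0, arabinose=1.0)


def perturb_params(params, rng, fraction=0.5):
    """Random +/-fraction perturbation of every free parameter."""
    free = params.free_values()
    u = rng.uniform(1 - fraction, 1 + fraction, size=free.shape)
    return params.with_free_values(free * u)
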