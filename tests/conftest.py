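import numpy as np
import pytest

from vclamp.simulate import ChannelEnsembleModel

# Generating parameter sets used across the suite (WT whole-cell fits,
# 15 mM charge carrier).
WT_CA_ACT = dict(act_v05_mv=1.48, act_k_mv=8.69, v_rev_mv=60.25)
WT_CA_INACT = dict(inact_v05_mv=-16.00, inact_k_mv=-6.73)
WT_BA_ACT = dict(act_v05_mv=-9.67, act_k_mv=7.74, v_rev_mv=43.25)


@pytest.fixture
def wt_ca_iv_model():
    """Noiseless, leak-free, non-inactivating WT Ca model for I-V round trips."""
    return ChannelEnsembleModel(
        **WT_CA_ACT, i_ss=1.0, tau_act_ms=0.2, q_gating_e0=0.0
    )


@pytest.fixture
def wt_ca_ssi_model():
    return ChannelEnsembleModel(
        **WT_CA_ACT, **WT_CA_INACT, i_ss=0.0,
        tau_act_ms=0.02, tau_inact_ms=300.0, q_gating_e0=0.0,
    )


@pytest.fixture
def nsfa_model():
    """N=1000, i = -0.5 pA at -49 mV, P0 = 0.8, b = 4 pA^2."""
    gamma = 0.5 * 1000.0 / (60.25 + 49.0)
    return ChannelEnsembleModel(
        n_channels=1000, gamma_ps=gamma, p_open_max=0.8, tau_act_ms=2.0,
        i_ss=1.0, noise_sd_pa=2.0, q_gating_e0=0.0, seed=42, **WT_CA_ACT,
    )
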