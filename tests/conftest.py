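import numpy as np
import pytest

from hsnphys import BoltzmannParams, ChannelModel, GHKSettings, IntervalModelParams

# printed steady-state gating midpoints for wild-type and P262S-mutant Cav3.1
WT_ACT = BoltzmannParams(v_half=-37.14, k=5.0, sense="activation")
MUT_ACT = BoltzmannParams(v_half=-44.69, k=5.0, sense="activation")
WT_INACT = BoltzmannParams(v_half=-58.18, k=4.0, sense="inactivation")
MUT_INACT = BoltzmannParams(v_half=-63.11, k=4.0, sense="inactivation")

ACT_GRID = np.arange(-80.0, 10.0 + 1e-9, 10.0)
INACT_GRID = np.arange(-100.0, -30.0 + 1e-9, 5.0)


@pytest.fixture
def interval_params():
    """Reference interval-model parameters: mean interval 11.0 min."""
    return IntervalModelParams(p=0.5, a=1.0, b=0.1)


@pytest.fixture
def ghk():
    return GHKSettings()


@pytest.fixture
def channel_model():
    return ChannelModel(scale=1e-6, act=WT_ACT, inact=WT_INACT, tau_m=5.0, tau_h=30.0)
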