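import warnings

import numpy as np
import pytest

from iedtools import synth
from iedtools.types import ChannelInfo, SessionBundle, SessionMeta, StateIntervals

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def short_session():
    """5-minute all-NREM session with default event statistics."""
    params = synth.GenParams(duration_s=300.0)
    return synth.generate_session(params, seed=42)


@pytest.fixture(scope="session")
def default_session():
    """20-minute session with the default NREM/REM/WAKE schedule."""
    params = synth.GenParams(duration_s=1200.0)
    return synth.generate_session(params, seed=1)


@pytest.fixture(scope="session")
def quiet_session():
    """Event-free 5-minute NREM session (background only)."""
    params = synth.GenParams(
        duration_s=300.0,
        hc_ied_rate_per_min=0.0,
        p_couple=0.0,
        down_background_rate_per_min=0.0,
        spindle_background_rate_per_min=0.0,
        ind_mpfc_ied_rate_per_min=0.0,
        n_pyr=0,
        n_int=0,
    )
    return synth.generate_session(params, seed=9)


def make_noise_bundle(
    n_channels=2, duration_s=300.0, fs=1250.0, sd=40.0, seed=0, state="NREM"
):
    """Plain white-noise bundle for detector/coherence null tests."""
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    lfp = rng.normal(0.0, sd, (n, n_channels))
    regions = ["HC", "MPFC", "OTHER", "OTHER"]
    channels = [
        ChannelInfo(f"ch{i}", regions[min(i, 3)], "LFP", 0.2) for i in range(n_channels)
    ]
    meta = SessionMeta("noise", fs, n, channels)
    states = StateIntervals([(0.0, duration_s, state)])
    return SessionBundle(meta=meta, lfp=lfp, states=states)


@pytest.fixture()
def noise_bundle():
    return make_noise_bundle()
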