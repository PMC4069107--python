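import numpy as np
import pytest

from gridphase import pipeline as pl
from gridphase import synthetic as syn


@pytest.fixture(scope="session")
def noisy_session():
    """600 s foraging session with moderate phase noise, true slope -8 deg/cm."""
    gt = syn.SyntheticGroundTruth(true_slope=-8.0, phase_noise_kappa=4.0)
    traj, lfp, spikes, gt = syn.simulate_session(600.0, gt=gt, seed=11)
    return traj, lfp, spikes, gt


@pytest.fixture(scope="session")
def noisy_result(noisy_session):
    traj, lfp, spikes, _ = noisy_session
    return pl.analyze_session(traj, spikes.t, lfp.lfp)


@pytest.fixture(scope="session")
def noiseless_session():
    """300 s session with exact phase law (kappa=inf), fixed entry phase."""
    gt = syn.SyntheticGroundTruth(
        true_slope=-10.0, phase_noise_kappa=np.inf,
        phase_offset_mode="fixed", entry_phase_deg=200.0,
    )
    traj, lfp, spikes, gt = syn.simulate_session(300.0, gt=gt, seed=5)
    return traj, lfp, spikes, gt
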