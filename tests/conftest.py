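import numpy as np
import pytest

from mstate import synth
from mstate.io_preprocess import Recording


@pytest.fixture(scope="session")
def templates3():
    """Three planted 9-channel topographies with bounded mutual correlation."""
    return synth.make_templates(3, 9, max_abs_corr=0.5, seed=1)


@pytest.fixture(scope="session")
def noiseless_recording(templates3):
    plan = synth.SimPlan(snr=np.inf, seed=2)
    return synth.synthesize_recording(templates3, plan)


@pytest.fixture(scope="session")
def noisy_recording(templates3):
    plan = synth.SimPlan(snr=2.0, seed=3)
    return synth.synthesize_recording(templates3, plan)


def as_recording(sim) -> Recording:
    return Recording(data=sim.data, sampling_rate=sim.sampling_rate)
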