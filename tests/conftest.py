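import numpy as np
import pytest

from stripephot import preprocess as pp
from stripephot import synthetic as syn
from stripephot.session import TimeSeries


@pytest.fixture(scope="session")
def small_fear():
    """A compact fear session (short ITIs) shared by read-only tests."""
    design = syn.fear_design(seed=1, iti_s=60.0)
    return syn.generate_fear_session(design)


@pytest.fixture(scope="session")
def reward_session():
    design = syn.reward_design(seed=3)
    return syn.generate_reward_session(design)


@pytest.fixture(scope="session")
def opto_session():
    design = syn.opto_design(seed=5)
    return syn.generate_opto_session(design)


@pytest.fixture()
def constant_dff():
    """A flat 100 Hz dF/F trace, 120 s long."""
    ts = TimeSeries(np.zeros(12000), 100.0, unit="% dF/F")
    return pp.DffTrace(ts, [], mode="whole_session")


def make_dff(values, fs=100.0, t0=0.0):
    return pp.DffTrace(TimeSeries(np.asarray(values, dtype=float), fs, t0, unit="% dF/F"),
                       [], mode="whole_session")
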