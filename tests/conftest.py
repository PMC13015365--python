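import numpy as np
import pytest

import placecode as pc
from placecode.synth import SimConfig, default_units, generate_session


@pytest.fixture(scope="session")
def demo_session():
    """80-trial mixed WT/KO session shared by the slower integration tests."""
    sim = SimConfig(n_trials=80, seed=7, units=default_units(4, 4), n_pulses=150)
    return generate_session(sim)


@pytest.fixture(scope="session")
def demo_bundle(demo_session):
    session, _ = demo_session
    return pc.run_pipeline(session, seed=11)
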