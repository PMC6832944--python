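import numpy as np
import pytest

import acticlust as ac


@pytest.fixture(scope="session")
def lab_study():
    """One simulated laboratory study: recording, bouts, labelled features."""
    cfg = ac.default_protocol(seed=3)
    rec, bouts = ac.simulate_recording(cfg)
    fm = ac.extract(rec, bouts, labelled_only=True)
    return rec, bouts, fm


@pytest.fixture(scope="session")
def lab_model(lab_study):
    """Portable model fitted on the simulated laboratory study."""
    _, _, fm = lab_study
    model, assignments = ac.fit_portable_model(fm, seed=3)
    return model, assignments


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
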