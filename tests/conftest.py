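import numpy as np
import pytest

from faceconn.cohort import default_ground_truth
from faceconn.model_space import enumerate_model_space
from faceconn.params import DCMParameters
from faceconn.simulate import StimulusDesign


@pytest.fixture(scope="session")
def faces_space():
    return enumerate_model_space(["faces"])


@pytest.fixture(scope="session")
def truth():
    return default_ground_truth()


def boxcar_design(tr=2.0, n_scans=100, ratio=8, on_s=16.0, off_s=8.0,
                  extra_inputs=()):
    """Simple faces on/off design for unit tests."""
    dt = tr / ratio
    n_micro = n_scans * ratio
    u = np.zeros(n_micro)
    t, on = 0, True
    while t < n_micro:
        dur = int(round((on_s if on else off_s) / dt))
        if on:
            u[t:t + dur] = 1.0
        t += dur
        on = not on
    inputs = {"faces": u}
    for name in extra_inputs:
        inputs[name] = np.zeros(n_micro)
    return StimulusDesign(dt=dt, inputs=inputs)


@pytest.fixture(scope="session")
def small_design():
    return boxcar_design()


@pytest.fixture(scope="session")
def pooled_mean_params(truth) -> DCMParameters:
    """Population-mean parameters restricted to the faces input."""
    from faceconn.cohort import _restrict_modulators
    return _restrict_modulators(truth.mean, ())
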