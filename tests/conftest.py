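import numpy as np
import pytest

from gabagamma.containers import TrialSet
from gabagamma.forward import leadfield
from gabagamma.geometry import CohortGeometry
from gabagamma.pipeline import AnalysisScale
from gabagamma.synthetic_cohort import CohortConfig, make_cohort


@pytest.fixture(scope="session")
def geom():
    return CohortGeometry.reduced()


@pytest.fixture(scope="session")
def lf(geom):
    return leadfield(geom.head, geom.grid)


@pytest.fixture(scope="session")
def scale():
    return AnalysisScale.reduced()


@pytest.fixture(scope="session")
def cohort(geom):
    config = CohortConfig.calibrated(geom, seed=7)
    return config, make_cohort(config, geom)


def make_tone_trials(freq=64.0, amp=1e-13, n_trials=4, n_sensors=2,
                     srate=600.0, phase=0.0):
    """Sensor epochs carrying a pure sinusoid on every channel."""
    t = -0.2 + np.arange(round(srate)) / srate
    x = amp * np.cos(2 * np.pi * freq * t + phase)
    data = np.tile(x, (n_trials, n_sensors, 1))
    return TrialSet(data, np.zeros((n_trials, len(t))))
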