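import pytest

from comnet.params import STANDARD_COHERENCES, ModelParameters
from comnet.simulate import run_experiment


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def experiment_table(params):
    """A moderate simulated experiment shared across analysis tests.

    600 trials per coherence condition (3600 total) with the default
    calibrated parameters; seed fixed for reproducibility.
    """
    return run_experiment([(c, 600) for c in STANDARD_COHERENCES],
                          params, seed=1)
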