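import numpy as np
import pytest

from prepair.data import AcquisitionParams
from prepair.extract import SubTrSignal
from prepair.pipeline import run_prepair
from prepair.simulate import default_config, simulate_epi


def make_subtr(samples, rate, source="magnitude"):
    """Wrap raw samples into a SubTrSignal with uniform times."""
    samples = np.asarray(samples, dtype=float)
    times = np.arange(len(samples)) / rate
    return SubTrSignal(samples=samples, rate=rate, times=times, source=source)


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic run (seed 1) shared across tests."""
    series, truth = simulate_epi(default_config(seed=1))
    return series, truth


@pytest.fixture(scope="session")
def default_result(default_sim):
    """Pipeline output on the shared default run."""
    series, _ = default_sim
    return run_prepair(series)


@pytest.fixture()
def simple_params():
    return AcquisitionParams(tr_vol=1.0, n_slices=4, n_reps=50, mb_factor=1)
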