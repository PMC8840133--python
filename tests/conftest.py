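import numpy as np
import pytest

from deepmaldi.peak_shape import default_shape_model
from deepmaldi.synth import SyntheticTruth, tof_grid


@pytest.fixture(scope="session")
def shape():
    """The synthetic default width-trend model used across tests."""
    return default_shape_model()


@pytest.fixture(scope="session")
def grid():
    """A moderately sized TOF-like m/z grid over the acquisition range."""
    return tof_grid((3000.0, 30000.0), 40000)


def flat_truth(positions, amplitudes, shape, noise_sd=0.0, n_points=40000, seed=0,
               bumps=(), baseline=(0.0, 1e9, 0.0)):
    """Truth with no baseline/bumps unless requested: isolates the peak layer."""
    return SyntheticTruth(
        peak_positions=np.asarray(positions, float),
        amplitudes=np.asarray(amplitudes, float),
        shape=shape,
        bump_components=list(bumps),
        baseline_params=baseline,
        noise_sd=noise_sd,
        n_points=n_points,
        seed=seed,
    )
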