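import numpy as np
import pytest

from locomod.cp import CPOptions
from locomod.synthetic import (SyntheticSpec, bin_centers,
                               generate_ground_truth, synthesize_tensor)


def small_spec(nonneg=True, R=3, S=8, seed=0, n_subjects=3):
    """A small but structurally complete study design for unit tests."""
    profiles = ["speed_linear", "run_specific", "constant",
                "walk_specific", "constant", "speed_linear"][:R]
    return SyntheticSpec(
        n_channels=S, n_subjects=n_subjects, speeds=bin_centers(0.5, 2.5)[::2],
        R=R, modulation_profiles=profiles, nonneg=nonneg, seed=seed)


@pytest.fixture
def planted_nonneg():
    spec = small_spec(nonneg=True, R=3, S=8, seed=11)
    truth = generate_ground_truth(spec)
    tensor = synthesize_tensor(truth, noise_sd=0.0)
    return spec, truth, tensor


@pytest.fixture
def planted_unconstrained():
    spec = small_spec(nonneg=False, R=3, S=6, seed=12)
    truth = generate_ground_truth(spec)
    tensor = synthesize_tensor(truth, noise_sd=0.0)
    return spec, truth, tensor


@pytest.fixture
def quick_opts():
    return CPOptions(max_iter=300, tol=1e-10, n_restarts=3, seed=99)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
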