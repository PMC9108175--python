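import numpy as np
import pytest

from wristcut import RunConfig, builtin_activity_profiles, builtin_cutpoints
from wristcut.pipeline import evaluate_dataset
from wristcut.synth import generate_cohort, generate_participants


@pytest.fixture(scope="session")
def profiles():
    """Activity catalogue keyed by code."""
    return {p.code: p for p in builtin_activity_profiles()}


@pytest.fixture(scope="session")
def cutpoint_sets():
    """Built-in cut-point registry keyed by name."""
    return {s.name: s for s in builtin_cutpoints()}


@pytest.fixture(scope="session")
def participant():
    return generate_participants(1, seed=42)[0]


@pytest.fixture(scope="session")
def default_cohort():
    """The default 18 x 12 simulated study (seed fixed)."""
    return generate_cohort(seed=1)


@pytest.fixture(scope="session")
def default_evaluation(default_cohort):
    return evaluate_dataset(default_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A 2-participant cohort for I/O and CLI tests."""
    return generate_cohort(RunConfig(n_participants=2), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def static_orientation_signal(rng, n_orient=40, seg_s=15.0, fs=30.0, noise_g=0.002):
    """Still postures at random orientations: ideal autocalibration input."""
    segs = []
    for _ in range(n_orient):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        segs.append(u + noise_g * rng.standard_normal((int(seg_s * fs), 3)))
    return np.concatenate(segs)
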