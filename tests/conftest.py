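import numpy as np
import pytest

from emograph import GeneratorSpec, extract_features, generate_dataset


def _features(coupling, periph, mode, seed):
    spec = GeneratorSpec(
        n_subjects=4,
        n_trials_per_subject=16,
        trial_length_s=10.0,
        coupling_effect=coupling,
        peripheral_effect=periph,
        mechanism_mode=mode,
        seed=seed,
    )
    return extract_features(generate_dataset(spec))


@pytest.fixture(scope="session")
def planted_features():
    """Strong shared-mechanism class signal (coupling + peripheral shift)."""
    return _features(0.7, 2.0, "shared", 1)


@pytest.fixture(scope="session")
def null_features():
    """No planted effect at all: labels are pure noise."""
    return _features(0.0, 0.0, "shared", 2)


@pytest.fixture(scope="session")
def idiosyncratic_features():
    """Strong effects whose direction is randomized per subject."""
    return _features(0.7, 2.0, "idiosyncratic", 3)


@pytest.fixture(scope="session")
def small_recordings():
    spec = GeneratorSpec(
        n_subjects=2, n_trials_per_subject=4, trial_length_s=6.0, seed=0
    )
    return generate_dataset(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
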