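import numpy as np
import pytest

from oncotext.simulate import GeneratorConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_corpus():
    """120-patient rendered corpus shared by unit tests."""
    return simulate_cohort(GeneratorConfig(n_patients=120, seed=42))


@pytest.fixture(scope="session")
def label_corpus():
    """500-patient unrendered corpus (labels only) for survival tests."""
    return simulate_cohort(
        GeneratorConfig(n_patients=500, seed=314), render_text=False
    )


@pytest.fixture(scope="session")
def clean_small_corpus():
    """Noise-free, distractor-free rendered corpus (60 patients)."""
    return simulate_cohort(
        GeneratorConfig(n_patients=60, seed=7, label_noise=0.0, lexicon_overlap=0.0)
    )


def rng(seed=0):
    return np.random.default_rng(seed)
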