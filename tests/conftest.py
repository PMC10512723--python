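import numpy as np
import pytest

from amyvox.cohort_synth import SynthConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic cohort (52 x 88) with planted effects."""
    return generate_cohort(SynthConfig(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for cheap tests: 5 acoustic columns, 1 planted."""
    cfg = SynthConfig(
        n_acoustic=5,
        informative_features=("F0semitoneFrom27.5Hz_sma3nz_amean",),
        seed=7,
    )
    return generate_cohort(cfg)


def separable_data(rng, n=60, p=8, n_informative=2, delta=3.0):
    """Two Gaussian classes separated by delta SDs on the informative columns."""
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, p))
    X[y == 1, :n_informative] += delta
    return X, y
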