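import pytest

from anhcascade.synthetic_fixtures import (
    FixtureSpec,
    make_harmonic_system,
    make_toy_anharmonic,
    rng_from_seed,
)
from anhcascade.vib_model import VibrationalSystem


@pytest.fixture
def rng():
    return rng_from_seed(12345)


@pytest.fixture
def one_mode_harmonic():
    return make_harmonic_system([1000.0])


@pytest.fixture
def one_mode_anharmonic():
    """nu = 1000, X11 = -10: the hand-checked single-mode reference."""
    return VibrationalSystem([1000.0], [[-10.0]], [1.0])


@pytest.fixture
def two_mode_system():
    """nu = (1000, 1500), X = [[-10, -5], [-5, -12]] with unit intensities
    and weak multi-quantum base intensities for line-table tests."""
    return VibrationalSystem(
        frequencies=[1000.0, 1500.0],
        x_matrix=[[-10.0, -5.0], [-5.0, -12.0]],
        intensities_fund=[1.0, 1.0],
        intensities_overtone=[0.1, 0.1],
        intensities_comb=[[0.0, 0.2], [0.2, 0.0]],
    )


@pytest.fixture
def toy3():
    """Default 3-mode anharmonic oracle system (enumerable)."""
    return make_toy_anharmonic(FixtureSpec(n_modes=3, freq_range=(300.0, 900.0), seed=7))
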