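import numpy as np
import pytest

from facedim import PopulationSpec, make_face_template


@pytest.fixture(scope="session")
def template():
    return make_face_template("oval")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Small two-sex population with default (study-scale) dimorphism."""
    return PopulationSpec(name="test", n_female=15, n_male=15, seed=7)


def random_similarity(rng):
    """Random rotation/positive-scale/translation triple."""
    theta = rng.uniform(-np.pi, np.pi)
    scale = rng.uniform(0.2, 5.0)
    shift = rng.uniform(-20, 20, size=2)
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, s], [-s, c]])
    return R, scale, shift
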