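import numpy as np
import pytest

from synkey.handmodel import HandGeometry
from synkey.synthetic import PopulationSpec, RenderSpec, make_population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def geometry():
    return HandGeometry()


@pytest.fixture(scope="session")
def render_spec():
    return RenderSpec()


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated population: 4 subjects, 8 objects, quick to score."""
    spec = PopulationSpec(
        n_subjects=4,
        objects=[f"obj-{i}" for i in range(8)],
        repetitions=3,
        n_followup_subjects=1,
        followup_sessions=2,
        seed=7,
    )
    return make_population(spec)


@pytest.fixture(scope="session")
def default_sim():
    """The reference-protocol population (10 subjects, 25 objects, 3 reps)."""
    return make_population(PopulationSpec(seed=1))
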