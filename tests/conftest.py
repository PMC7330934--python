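import numpy as np
import pytest

from ihcquant.synthetic_ihc import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def default_scene():
    """One default scene (30 cells, 5 distractors, 10 specks), shared read-only."""
    return generate_scene(SceneSpec(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
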