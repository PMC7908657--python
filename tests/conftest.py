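import numpy as np
import pytest

from mitodet.simulate import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic synthetic scene shared across read-only tests."""
    spec = SceneSpec(seed=7)
    volume, annotations = generate_scene(spec)
    return spec, volume, annotations


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
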