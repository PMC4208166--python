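import numpy as np
import pytest

from leukoseg import synth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def simple_scene():
    """One seeded scene: clean geometry, mild noise, no cast."""
    spec = synth.SceneSpec(seed=3)
    return synth.generate(spec)


@pytest.fixture(scope="session")
def flat_scene():
    """Noise-free, cast-free, single-WBC, no-RBC scene: exactly 3 colors."""
    spec = synth.SceneSpec(
        seed=5, n_rbc=0, n_wbc=1, noise_std=0.0, color_jitter_std=0.0
    )
    return synth.generate(spec)
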