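import numpy as np
import pytest

from fingergonio import SceneSpec, render_scene


@pytest.fixture(scope="session")
def clean_scene():
    """Noise- and texture-free render of the canonical flexed pose."""
    spec = SceneSpec(angles=(145.0, 110.0, 115.0), noise_sigma=0.0,
                     texture_amplitude=0.0, seed=1)
    return render_scene(spec)


@pytest.fixture(scope="session")
def noisy_scene():
    """Default-condition render (sensor noise + skin texture + ramp)."""
    spec = SceneSpec(angles=(145.0, 110.0, 115.0), seed=7)
    return render_scene(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
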