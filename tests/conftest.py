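import numpy as np
import pytest

from mtsaquant.synthetic import RenderConfig, default_spectral_library, generate_scene


@pytest.fixture(scope="session")
def panel2_library():
    return default_spectral_library(panel=2)


@pytest.fixture(scope="session")
def panel1_library():
    return default_spectral_library(panel=1)


@pytest.fixture(scope="session")
def small_scene():
    """A compact panel-II scene with planted co-localization."""
    return generate_scene(
        {"CD4": 40, "CD68": 20, "CD163": 6},
        {("CD68", "CD163"): 0.5, ("CD4", "GATA3"): 0.25},
        scene_size_um=300.0,
        seed=7,
        capillary_fraction=0.0,
    )


@pytest.fixture(scope="session")
def small_render(panel2_library):
    return RenderConfig(library=panel2_library)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
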