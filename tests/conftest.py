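import numpy as np
import pytest

from nanosense import scene_sim


@pytest.fixture(scope="session")
def paraboloid_scene() -> scene_sim.Scene:
    phantom = scene_sim.CellPhantom(
        center=(64.0, 64.0),
        semi_axes=(30.0, 30.0),
        h_max=5.0,
        delta_n=0.02,
        profile_kind="paraboloid",
    )
    return scene_sim.Scene(
        phantoms=(phantom,), background_intensity=150.0, image_shape=(128, 128)
    )


@pytest.fixture(scope="session")
def clean_scene() -> scene_sim.Scene:
    """12 well-separated ellipsoid phantoms, no noise."""
    return scene_sim.grid_scene(12, image_shape=(256, 320), seed=3, noise_sigma=0.0)


@pytest.fixture(scope="session")
def noisy_scene() -> scene_sim.Scene:
    return scene_sim.grid_scene(20, image_shape=(256, 320), seed=7, noise_sigma=1.0)


@pytest.fixture(scope="session")
def z_list() -> np.ndarray:
    return np.arange(-50.0, 245.0 + 2.5, 5.0)  # 60 planes, 5 um step


@pytest.fixture(scope="session")
def noisy_stack(noisy_scene, z_list):
    return scene_sim.render_zstack(noisy_scene, z_list)


@pytest.fixture(scope="session")
def tip_stage() -> scene_sim.TipStage:
    tip = scene_sim.TipPhantom(apex=(128.0, 160.0))
    return scene_sim.TipStage(tip, shape=(256, 320))
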