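import numpy as np
import pytest
from hypothesis import settings

from fiberaif import (
    TransportConfig,
    build_human_wrist_scene,
    build_mouse_tail_scene,
    build_validation_tube_scene,
    simulate_positron_source,
    simulate_scene,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg_small():
    return TransportConfig(n_histories=8_000, seed=11)


@pytest.fixture(scope="session")
def mouse_f18(cfg_small):
    """Mouse-tail scene result (F18), vessels + importance-sampled body."""
    scene = build_mouse_tail_scene("F18")
    return simulate_scene(scene, "F18", cfg_small, include_background=True,
                          n_background_decays=200_000)


@pytest.fixture(scope="session")
def mouse_ga68(cfg_small):
    scene = build_mouse_tail_scene("Ga68")
    return simulate_scene(scene, "Ga68", cfg_small, include_background=False)


@pytest.fixture(scope="session")
def tube_f18(cfg_small):
    scene = build_validation_tube_scene("F18")
    return simulate_positron_source(scene, "F18", "source_artery", cfg_small)


@pytest.fixture(scope="session")
def wrist_ga68(cfg_small):
    scene = build_human_wrist_scene("Ga68", vessel_depth_mm=2.0, n_fibers=1,
                                    fiber_shape="round")
    return simulate_positron_source(scene, "Ga68", "source_artery", cfg_small)
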