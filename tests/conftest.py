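import numpy as np
import pytest

from flowquant import AcquisitionConfig, FrameStack, figure_example_scene, generate_field_stack


@pytest.fixture(scope="session")
def config():
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def figure_stack(config):
    """Noiseless single-field worked example: 10 in-focus cells, 6 stationary."""
    scene = figure_example_scene(config, seed=1)
    return generate_field_stack(scene, config, noise_sigma=0.0, seed=1)


@pytest.fixture(scope="session")
def small_config():
    """A tiny acquisition for cheap pixel-level checks (5 frames, 20x24 px)."""
    return AcquisitionConfig(
        frame_rate=5, duration_s=1.0,
        field_width_um=24, field_height_um=20,
    )


def random_small_stack(rng, small_config, max_gray=255):
    frames = rng.integers(0, max_gray + 1,
                          size=(small_config.n_frames, *small_config.shape),
                          dtype=np.uint8 if max_gray <= 255 else np.uint16)
    return FrameStack(frames=frames, config=small_config)
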