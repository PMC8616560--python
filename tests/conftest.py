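import numpy as np
import pytest

from golgikin.synthetic import (
    MarkerSpec,
    SimConfig,
    noise_free,
    simulate_coloc_snapshot,
    simulate_maturation_movie,
)


@pytest.fixture(scope="session")
def clean_pair_movie():
    """Noise-free two-marker movie (zero offset), 4 puncta, with ground truth."""
    cfg = noise_free(SimConfig(image_shape=(128, 128), n_puncta=4, seed=7))
    markers = [MarkerSpec("green", 0.0, 10.0), MarkerSpec("red", 0.0, 10.0)]
    return simulate_maturation_movie(cfg, markers)


@pytest.fixture(scope="session")
def clean_snapshot():
    """Noise-free snapshot: 10 coincident puncta, with ground truth."""
    cfg = noise_free(SimConfig(image_shape=(128, 128), n_puncta=10, seed=3))
    return simulate_coloc_snapshot(cfg, n_coincident=10, n_green_only=0, n_red_only=0)


@pytest.fixture()
def constant_spot_movie():
    """Hand-built movie: one always-on Gaussian spot, both channels, 61 frames."""
    ny = nx = 64
    yy, xx = np.mgrid[0:ny, 0:nx]
    spot = 500.0 * np.exp(-((yy - 30.0) ** 2 + (xx - 33.0) ** 2) / (2 * 1.5**2))
    frame = np.stack([spot, spot])
    data = np.tile(frame, (61, 1, 1, 1))
    from golgikin.synthetic import MovieStack

    return MovieStack(data, frame_interval=2.0, channel_names=["green", "red"])
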