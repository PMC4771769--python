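"""Shared fixtures: small synthetic scenes reused across test modules."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helpers

from aisquant.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A compact three-channel scene (subunit + AnkG + gephyrin), 4 ROI pairs."""
    cfg = SceneConfig(
        image_size_px=(320, 320), pixel_size_nm=128.0, n_ais=4,
        ais_length_um=12.0, ais_width_um=1.6, ais_wiggle_um=0.5,
        channels=("alpha2", "AnkG", "Geph"), seed=7,
    )
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def clean_scene():
    """A noise-free, blur-free scene for exact planted-vs-measured checks."""
    cfg = SceneConfig(
        image_size_px=(320, 320), pixel_size_nm=128.0, n_ais=4,
        ais_length_um=12.0, ais_width_um=1.6, ais_wiggle_um=0.5,
        channels=("alpha2",), poisson_noise=False, gaussian_read_sd=0.0,
        background_gradient_amplitude=0.0, psf_sigma_um=0.0, seed=11,
    )
    return generate_scene(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
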