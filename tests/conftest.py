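"""Shared fixtures: small-field configs and pre-rendered movies.

Rendering fixtures use a 30x30 um field (8 nuclei at cycle-13 density) so the
image-based tests stay fast; the acceptance suite uses the full 60x60 um field.
"""

from dataclasses import replace

import pytest

from furrowdyn import default_configs
from furrowdyn.render import render_movie

SMALL_AREA = 900.0  # um^2


@pytest.fixture(scope="session")
def wt_configs():
    return default_configs("WT")


@pytest.fixture(scope="session")
def wt13_small(wt_configs):
    return replace(wt_configs[13], field_area=SMALL_AREA)


@pytest.fixture(scope="session")
def wt13_small_clean(wt_configs):
    return replace(wt_configs[13], field_area=SMALL_AREA, depth_noise_sd=0.0)


@pytest.fixture(scope="session")
def wt13_movie_clean(wt13_small_clean):
    """Noise-free rendered WT cycle-13 movie (ground truth oracle attached)."""
    return render_movie(wt13_small_clean, seed=5, camera_noise=False)


@pytest.fixture(scope="session")
def wt13_movie_noisy(wt13_small):
    return render_movie(wt13_small, seed=11)


@pytest.fixture(scope="session")
def fragmented_movie_clean():
    """Broken-furrow (aneuploid-X preset) rendering, noise off."""
    cfg = replace(default_configs("aneuploid_X")[13], field_area=SMALL_AREA,
                  depth_noise_sd=0.0)
    return cfg, render_movie(cfg, seed=7, camera_noise=False)
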