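"""Shared fixtures: small synthetic panels generated at test time."""

import numpy as np
import pytest

from berrymorph import synth

#: coarse scale used by most tests; keeps rasters ~150 px across
TEST_SCALE = 0.2


@pytest.fixture(scope="session")
def small_panel():
    """Three well-separated varieties, one per family, 8 berries each."""
    configs = [
        synth.VarietyConfig("Sph", "sphere", 24.0, 0.8, 23.5, 0.8, 23.5, 0.8),
        synth.VarietyConfig("Ell", "ellipse", 32.0, 0.8, 21.0, 0.8, 21.5, 0.8),
        synth.VarietyConfig("Drp", "drop", 30.0, 0.8, 22.0, 0.8, 22.5, 0.8, asym=0.35),
    ]
    configs = [
        synth.VarietyConfig(**{**c.__dict__, "n_berries": 8}) for c in configs
    ]
    masks, truth = synth.generate_dataset(configs, master_seed=7, scale=TEST_SCALE)
    return masks, truth


@pytest.fixture(scope="session")
def circle_mask():
    """Digitized disk of radius 10 mm at 0.05 mm/px (r = 200 px)."""
    poly = synth.make_outline(synth.OutlineSpec("circle", 20.0, 20.0))
    return synth.rasterize(poly, 0.05)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
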