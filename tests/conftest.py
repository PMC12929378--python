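import numpy as np
import pytest

from fieldseg.synth import FieldParams, filter_negative_tiles, generate_field, tile_scene


@pytest.fixture(scope="session")
def small_scene():
    """A 1440×960 scene — ~4.7 m × 3.1 m of ground at the default GSD."""
    return generate_field(FieldParams(width_px=1440, height_px=960), seed=7)


@pytest.fixture(scope="session")
def small_tiles(small_scene):
    return filter_negative_tiles(tile_scene(small_scene, size=96, stride=96))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
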