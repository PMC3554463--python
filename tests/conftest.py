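import numpy as np
import pytest

from histograph.imageprep import LabelMask
from histograph.retrieval import IndexConfig, build_database
from histograph.synthdata import generate_dataset, standard_tile_mixture

# preparation settings matched to 64-px synthetic tiles: masks are speck-free
# by construction, so a radius-1 element and a small area floor suffice
SYNTH_INDEX_CONFIG = IndexConfig(
    tile_size=64, overlap=0.0, struct_radius=1, min_area=8
)


@pytest.fixture(scope="session")
def small_tile_db():
    """20 mixed-motif 64-px tiles indexed with ground-truth metadata."""
    tiles = generate_dataset(standard_tile_mixture(64), 20, seed=101)
    index = build_database(
        [m for m, _ in tiles], SYNTH_INDEX_CONFIG, metas=[md for _, md in tiles]
    )
    return tiles, index


@pytest.fixture
def stripes_mask():
    """Three equal vertical stripes labeled 1|2|3 on a 9x9 grid."""
    px = np.repeat(np.array([[1, 2, 3]], dtype=np.int32), 9, axis=0)
    return LabelMask(np.repeat(px, 3, axis=1))


def random_label_mask(rng, shape=(24, 24), n_labels=4, p_background=0.15):
    """Small random mask with background for partition property tests."""
    px = rng.integers(0, n_labels + 1, size=shape)
    px[rng.uniform(size=shape) < p_background] = 0
    return LabelMask(px.astype(np.int32), n_labels=n_labels)
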