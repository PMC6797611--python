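import numpy as np
import pytest

import brainglance as bg


@pytest.fixture
def phantom():
    """Small mirror-symmetric phantom: 16^3 grid, 8 areas (2 gross x 2 x 2 hemi)."""
    spec = bg.PhantomSpec(
        grid_shape=(16, 16, 16),
        n_gross_regions=2,
        areas_per_region_per_hemisphere=2,
        seed=0,
    )
    atlas, definition = bg.make_phantom_atlas(spec)
    return atlas, definition


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_symmetric_definition(rng, n_gross=None, areas_per=None):
    """Random atlas definition where every L area has an exact R partner."""
    n_gross = n_gross or int(rng.integers(1, 5))
    areas_per = areas_per or int(rng.integers(1, 5))
    definition = bg.AtlasDefinition()
    label = 0
    for hemi in ("L", "R"):
        for g in range(n_gross):
            for a in range(areas_per):
                label += 1
                definition.add_area(
                    bg.AtlasArea(label, f"G{g}_A{a}", f"G{g}", hemi)
                )
    return definition
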