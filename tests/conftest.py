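import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from yieldstab import Crop, GridTransform, YieldMap, YieldStack, build_stack, normalize_map


def make_map(values, mask=None, field_id="f1", year=2010, crop=Crop.MAIZE, pixel=30.0):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return YieldMap(values, mask, field_id=field_id, year=year, crop=crop,
                    transform=GridTransform(pixel_size=pixel))


def random_norm_stack(rng, shape=(20, 20), n_years=6, field_id="f1", mask_frac=0.0):
    """Random normalized stack; optionally knock out a fraction of pixels per year."""
    maps = []
    for t in range(n_years):
        vals = rng.normal(size=shape)
        mask = np.ones(shape, dtype=bool)
        if mask_frac > 0:
            mask &= rng.random(shape) > mask_frac
        m = make_map(vals, mask, field_id=field_id, year=2010 + t)
        maps.append(normalize_map(m))
    return build_stack(maps)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_stack(rng):
    return random_norm_stack(rng, shape=(8, 8), n_years=4)
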