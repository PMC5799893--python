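import numpy as np
import pytest
from hypothesis import settings

from nestmorph import ParticleMap, SpotImage

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def make_pmap(labels) -> ParticleMap:
    labels = np.asarray(labels, dtype=np.int32)
    return ParticleMap(labels=labels, n_particles=int(labels.max()))


def make_spot(pixels, spot_id="spot") -> SpotImage:
    return SpotImage(spot_id=spot_id, pixels=np.asarray(pixels, dtype=np.uint8))


def random_blob_mask(rng, shape=(64, 64), n_blobs=12, max_radius=4) -> np.ndarray:
    """Sprinkle random disks; overlaps merge into irregular particles."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_blobs):
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        r = rng.integers(1, max_radius + 1)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask


@pytest.fixture
def ring_5x5():
    """Ring spanning a 5x5 box: 16 foreground pixels enclosing a
    single-pixel centre hole (area 16 -> 17 once filled)."""
    ring = np.array(
        [
            [0, 0, 1, 0, 0],
            [1, 1, 1, 1, 1],
            [1, 1, 0, 1, 1],
            [1, 1, 1, 1, 1],
            [0, 0, 1, 0, 0],
        ],
        dtype=np.int32,
    )
    return make_pmap(np.pad(ring, 1))
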