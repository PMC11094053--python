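import numpy as np
import pytest

from cinefunc import phantom as ph


@pytest.fixture(scope="session")
def small_phantom():
    """One clean mid-size phantom shared by read-only tests."""
    cfg = ph.PhantomConfig(n_slices=5, n_phases=10, image_size=64,
                           endo_radius_px=10.0, wall_thickness_px=5.0,
                           contraction_fraction=0.3, empty_slice_margin=1,
                           seed=42)
    stack, gt = ph.generate_phantom_stack(cfg)
    return cfg, stack, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_annulus_mask(rng, size=48):
    """A random simply-connected cavity+myocardium mask for property tests."""
    yy, xx = np.mgrid[0:size, 0:size]
    cy, cx = rng.uniform(size * 0.35, size * 0.65, size=2)
    r = rng.uniform(4, size * 0.22)
    w = rng.uniform(2, size * 0.12)
    rr = np.hypot(yy - cy, xx - cx)
    mask = np.zeros((size, size), dtype=np.uint8)
    mask[rr <= r + w] = 2
    mask[rr <= r] = 1
    return mask
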