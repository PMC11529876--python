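import numpy as np
import pytest

from emma import fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_test_montage(
    seed,
    rows=2,
    cols=2,
    tile=128,
    overlap=0.3,
    jitter=0,
    shading=0.0,
    brightness=0.0,
    noise=0.0,
    bit_depth=8,
):
    """Phantom sized to the grid, sliced with the given corruption."""
    sspec = fixtures.SliceSpec(
        rows=rows,
        cols=cols,
        tile_width=tile,
        tile_height=tile,
        overlap_fraction=overlap,
        jitter_px=jitter,
        shading_amplitude=shading,
        brightness_jitter=brightness,
        noise_sigma=noise,
        seed=seed,
    )
    pspec = fixtures.PhantomSpec(seed=seed + 1000, bit_depth=bit_depth)
    return fixtures.make_montage(pspec, sspec)


@pytest.fixture
def clean_montage_2x2():
    """2x2 montage with no corruption at all (tiles reproduce the phantom)."""
    return make_test_montage(seed=11)


@pytest.fixture
def noisy_montage_3x3():
    """3x3 montage at the corruption level the recovery checks use."""
    return make_test_montage(
        seed=5, rows=3, cols=3, tile=256, jitter=8, shading=0.2, noise=5.0
    )
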