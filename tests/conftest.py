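import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from patchfuse import (
    DeformSpec,
    PhantomSpec,
    Primitive,
    make_library,
    make_phantom,
)
from patchfuse.phantom import sphere


def three_slab_spec(seed=11, means=(40.0, 120.0, 200.0), noise_sigma=5.0, n=64):
    """Three roughly equal-volume intensity classes on an n^3 grid.

    Background slab plus two box structures; balanced shares keep the
    percentile-based tissue-mean initialization meaningful, as in a real
    intracranial mask.
    """
    third = n // 3
    half = (n - 1) / 2.0
    b1_lo, b1_hi = third, 2 * third
    return PhantomSpec(
        grid_shape=(n, n, n),
        structures=[
            Primitive(
                1, "box",
                ((b1_lo + b1_hi) / 2.0, half, half),
                ((b1_hi - b1_lo) / 2.0, half, half),
                means[1], name="gm-slab",
            ),
            Primitive(
                2, "box",
                ((b1_hi + 1 + n - 1) / 2.0, half, half),
                ((n - 1 - b1_hi - 1) / 2.0, half, half),
                means[2], name="wm-slab",
            ),
        ],
        background_mean=means[0],
        noise_sigma=noise_sigma,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_phantom():
    """24^3 noisy two-class phantom (background 50, sphere 150)."""
    spec = PhantomSpec(
        grid_shape=(24, 24, 24),
        structures=[sphere(1, (12, 12, 12), 6.0, 150.0, name="ball")],
        background_mean=50.0,
        noise_sigma=5.0,
        seed=3,
    )
    img, lab = make_phantom(spec)
    return spec, img, lab


@pytest.fixture(scope="session")
def small_library(small_phantom):
    """Four deformed/noisy variants of the small phantom."""
    _, img, lab = small_phantom
    return make_library(
        img,
        lab,
        DeformSpec(
            n_templates=4,
            displacement_amplitude=1.5,
            displacement_smoothness=6.0,
            per_template_noise_sigma=5.0,
            seed=7,
        ),
    )


@pytest.fixture(scope="session")
def three_class_phantom():
    """64^3 balanced three-tissue phantom with class means 40/120/200."""
    spec = three_slab_spec(seed=11)
    img, lab = make_phantom(spec)
    return spec, img, lab


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160730)
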