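import numpy as np
import pytest

from priorimap.grid import Grid
from priorimap.landsim import generate_landscape, true_surfaces
from priorimap.layers import build_stack
from priorimap.scenarios import demo_landscape_config, demo_response


@pytest.fixture(scope="session")
def demo_landscape():
    """Small (60x60) demo landscape shared by read-only tests."""
    return generate_landscape(demo_landscape_config(60, 60, seed=5))


@pytest.fixture(scope="session")
def demo_stack(demo_landscape):
    return build_stack(demo_landscape)


@pytest.fixture(scope="session")
def demo_truth(demo_landscape, demo_stack):
    return true_surfaces(demo_landscape, demo_response(), stack=demo_stack)


def random_grid(rng, shape=(10, 12), pixel_size=30.0, low=0.0, high=1.0,
                nodata_frac=0.0):
    values = rng.uniform(low, high, size=shape)
    nodata = rng.random(shape) < nodata_frac
    return Grid(values=values, pixel_size=pixel_size, origin=(0.0, 0.0), nodata=nodata)


def random_binary_grid(rng, shape=(20, 20), p=0.2, pixel_size=30.0):
    return Grid(values=(rng.random(shape) < p).astype(float), pixel_size=pixel_size)
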