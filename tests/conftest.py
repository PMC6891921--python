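import numpy as np
import pytest

from vesselquant import phantom as ph


@pytest.fixture(scope="session")
def straight_tube():
    """Single horizontal tube, radius 5 px, length 100 px, in 256x256."""
    spec = ph.PhantomSpec(
        branches=[ph.TubeBranch(points=((128.0, 78.0), (128.0, 178.0)), radius_px=5.0)]
    )
    stack, truth = ph.generate_network_phantom(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def tree_phantom():
    """Seeded random vessel tree with junctions (noise-free)."""
    spec = ph.random_tree_network(seed=2)
    stack, truth = ph.generate_network_phantom(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def leakage_vessel():
    """Single perfused vessel used for leakage simulations."""
    spec = ph.single_vessel_phantom(radius_px=10.0)
    _, truth = ph.generate_network_phantom(spec)
    return truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
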