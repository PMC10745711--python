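import numpy as np
import pytest

import vasckit as vk


@pytest.fixture(scope="session")
def bar():
    """500×40 μm flat-capped bar at 1 μm/px: area exactly 20,000 μm²."""
    return vk.bar_mask(500.0, 40.0, pixel_size=1.0)


@pytest.fixture(scope="session")
def bar_graph(bar):
    return vk.skeletonize_network(bar)


@pytest.fixture(scope="session")
def h_fixture():
    """H-shaped network: 2 junctions, 4 endpoints, 5 branches."""
    return vk.h_mask(height=400.0, span=200.0, width=20.0, pixel_size=1.0)


@pytest.fixture(scope="session")
def network():
    spec = vk.SyntheticNetworkSpec(seed=1, n_nodes=12, pixel_size=1.0,
                                   domain_size=(400.0, 400.0))
    return vk.generate_vessel_network(spec)


@pytest.fixture(scope="session")
def frap_movie():
    """Noiseless free-diffusion recovery at the fibrin-gel diffusivity."""
    return vk.simulate_frap(D_true=34.5, spot_diameter=30.0,
                            frame_interval=0.4, n_frames=60, seed=0)
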