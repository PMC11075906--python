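import numpy as np
import pytest

from cmqtl import simulate as sim

SCREEN_DOSES = np.array([0.0, 0.01, 0.1, 0.75, 1.0, 1.25, 2.0, 5.0])


@pytest.fixture(scope="session")
def small_map():
    return sim.simulate_marker_map(3, 40, 100_000_000, seed=11)


@pytest.fixture(scope="session")
def small_genoprobs(small_map):
    _, gp = sim.simulate_do_genoprobs(150, small_map, seed=13)
    return gp


@pytest.fixture(scope="session")
def tiny_genoprobs():
    mm = sim.simulate_marker_map(2, 6, 50_000_000, seed=3)
    _, gp = sim.simulate_do_genoprobs(12, mm, seed=5)
    return gp
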