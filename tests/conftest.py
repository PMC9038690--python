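import numpy as np
import pytest

from crossfeed.lattice_domain import (
    CONSUMER,
    EMPTY,
    PRODUCER,
    Occupancy,
    build_lattice,
)


@pytest.fixture(scope="session")
def small_lattice():
    """~100 µm disk, 7-ish rings of nodes."""
    return build_lattice(400.0, 20.0)


@pytest.fixture(scope="session")
def mid_lattice():
    return build_lattice(1200.0, 20.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_blob(lattice, rng, n_occupied, p_consumer=0.3, seed_node=None):
    """Random connected occupied blob grown from the centre node."""
    center = int(np.argmin(lattice.radii())) if seed_node is None else seed_node
    occ = Occupancy.empty(lattice)
    frontier = [center]
    chosen = {center}
    while len(chosen) < n_occupied and frontier:
        u = frontier[rng.integers(len(frontier))]
        nbrs = [int(v) for v in lattice.neighbors[u] if v >= 0 and int(v) not in chosen]
        if not nbrs:
            frontier.remove(u)
            continue
        v = nbrs[rng.integers(len(nbrs))]
        chosen.add(v)
        frontier.append(v)
    nodes = np.array(sorted(chosen))
    occ.strain[nodes] = np.where(rng.random(nodes.size) < p_consumer, CONSUMER, PRODUCER)
    occ.biomass[nodes] = 1e-14
    return occ


@pytest.fixture
def blob_factory():
    return make_blob
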