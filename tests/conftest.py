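import numpy as np
import pytest

from cellreservoir.experiments import build_reservoir
from cellreservoir.geometry import build_cell, generate_cytoskeleton
from cellreservoir.reservoir import assign_conductance, build_graph


@pytest.fixture
def small_cell():
    """A 17^3 cell (1 μm voxels, radii 8/7/2 μm) for fast unit tests."""
    return build_cell(voxel_size=1.0, r_cm=8.0, r_pc=7.0, r_co=2.0)


@pytest.fixture(scope="session")
def reference_cell():
    """The reference 41^3 cell (0.5 μm voxels, radii 10/9/2.5 μm)."""
    return build_cell(voxel_size=0.5, r_cm=10.0, r_pc=9.0, r_co=2.5)


@pytest.fixture(scope="session")
def reference_graph():
    """Reference reservoir: 41^3 cell, 20% fill, log-normal conductances.

    Session-scoped and treated as read-only occupancy/conductance; the
    mutable I/S fields are reset by run_sequence itself.
    """
    return build_reservoir(geometry_seed=3, conductance_seed=4)


def small_random_graph(seed, cs_fraction=0.25):
    """A randomly filled small conducting graph for oracle comparisons."""
    geom = build_cell(voxel_size=1.0, r_cm=8.0, r_pc=7.0, r_co=2.0)
    generate_cytoskeleton(geom, cs_fraction, seed)
    graph = build_graph(geom)
    assign_conductance(graph, seed=seed + 1)
    return graph
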