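"""Small deterministic geometries for exact-step tests and demos."""

from __future__ import annotations

import numpy as np

from .geometry import CellGeometry, Region, build_cell, generate_cytoskeleton
from .reservoir import ReservoirGraph, assign_conductance, build_graph

FIXTURE_KINDS = ("tiny-percolating", "tiny-nonpercolating", "chain", "reference-geometry")


def make_fixture(kind: str, seed: int = 0) -> tuple[CellGeometry, ReservoirGraph]:
    """Build one of the named test objects.

    * ``chain`` — a straight cytoskeleton line from the PC shell to the
      CO ball along +x; with L chain voxels the organelle-surface arrival
      is exactly L+1 steps (one voxel per step: L chain voxels, then the
      first CO voxel).
    * ``tiny-nonpercolating`` — a cytoskeleton blob touching the PC shell
      but detached from the organelle: the front saturates without ever
      reaching the CO surface.
    * ``tiny-percolating`` — a small cell with a dense uniform fill,
      verified at build time to percolate.
    * ``reference-geometry`` — the reference 41^3 cell (81^3 reservoir
      tensor) with a 20% fill.
    """
    if kind == "chain":
        geom = build_cell(voxel_size=1.0, r_cm=8.0, r_pc=7.0, r_co=2.0)
        c = geom.center
        # CS voxels strictly between the CO ball (r=2) and PC shell (r=7)
        for i in range(c + 3, c + 7):
            geom.labels[i, c, c] = Region.CS
        geom.chain_length = 4  # type: ignore[attr-defined]
    elif kind == "tiny-nonpercolating":
        geom = build_cell(voxel_size=1.0, r_cm=8.0, r_pc=7.0, r_co=2.0)
        c = geom.center
        # blob adjacent to the PC shell, >1 voxel clear of the CO ball
        geom.labels[c + 5 : c + 7, c - 1 : c + 2, c] = np.where(
            geom.labels[c + 5 : c + 7, c - 1 : c + 2, c] == Region.CYTO,
            Region.CS,
            geom.labels[c + 5 : c + 7, c - 1 : c + 2, c],
        )
    elif kind == "tiny-percolating":
        geom = build_cell(voxel_size=1.0, r_cm=8.0, r_pc=7.0, r_co=2.0)
        generate_cytoskeleton(geom, 0.5, seed)
        graph = assign_conductance(build_graph(geom), seed=seed)
        from .experiments import percolates

        if not percolates(graph):  # pragma: no cover - 50% fill always connects
            raise RuntimeError("tiny-percolating fixture failed to percolate")
        return geom, graph
    elif kind == "reference-geometry":
        geom = build_cell(voxel_size=0.5, r_cm=10.0, r_pc=9.0, r_co=2.5)
        generate_cytoskeleton(geom, 0.20, seed)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    graph = assign_conductance(build_graph(geom), seed=seed)
    return geom, graph
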