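"""Grid-graph reservoir with doubled-index edge storage.

An ``n**3`` voxel grid is embedded in a ``(2n-1)**3`` tensor: voxel
``(i, j, k)`` becomes the vertex cell ``(2i, 2j, 2k)`` and the conductance
of the edge joining voxels ``x`` and ``x + d`` (``d`` one of the 26 unit
offsets) lives at the in-between cell ``2x + d``.  Every cell with at least
one odd coordinate is edge storage, which gives ``(2n-1)**3 - n**3 =
7n**3 - 12n**2 + 6n - 1`` storage cells for a full grid.  Crossing face
diagonals share a face-midpoint cell and the four body diagonals of a cell
cube share its center cell, so crossing edges share one conductance value —
a deliberate property of this storage scheme.

Each occupied vertex carries a physical signal ``I`` (aggregated current)
and a memory state ``S`` (exponential moving average of ``tanh(I)``); both
are stored as dense ``(n, n, n)`` arrays, zero off the occupied set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import _NEIGHBOR_OFFSETS, CellGeometry, ConfigurationError, Region

#: region codes that conduct by default: signals enter at the peripheral
#: cytoplasm, travel via cytoskeleton, and terminate at the central
#: organelle.  Membrane conduction is a configuration switch.
DEFAULT_CONDUCTION = frozenset({Region.PC, Region.CS, Region.CO})


def edge_storage_count(n: int) -> int:
    """Number of edge-storage cells of a full n**3 grid: (2n-1)**3 - n**3."""
    return (2 * n - 1) ** 3 - n**3


@dataclass
class ReservoirGraph:
    """Doubled-index reservoir tensor bound to a cell geometry."""

    geom: CellGeometry
    conduction_map: frozenset
    occupied: np.ndarray            # (n,n,n) bool — conducting voxels
    occupancy: np.ndarray           # (2n-1,)**3 uint8 — nonzero at even triples only
    conductance: np.ndarray | None = None  # (2n-1,)**3 float, odd cells
    I: np.ndarray = field(default=None)  # type: ignore[assignment]
    S: np.ndarray = field(default=None)  # type: ignore[assignment]
    conductance_seed: int | None = None
    _offset_cond: dict | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.geom.n

    @property
    def side(self) -> int:
        return 2 * self.n - 1

    def offset_conductance(self) -> dict[tuple[int, int, int], np.ndarray]:
        """Per-offset conductance gathered onto the voxel grid.

        ``result[d][x] == conductance[2x + d]`` for in-bounds neighbors and
        0 where ``x + d`` falls outside the grid.  Cached; used by the
        vectorized current computation.
        """
        if self.conductance is None:
            raise ConfigurationError("conductance not assigned yet")
        if self._offset_cond is None:
            shape = self.occupied.shape
            out = {}
            for d in _NEIGHBOR_OFFSETS:
                g = np.zeros(shape, dtype=self.conductance.dtype)
                dst, src = [], []
                for x, n in zip(d, shape):
                    if x == 0:
                        dst.append(slice(0, n))
                        src.append(slice(0, 2 * n - 1, 2))
                    elif x == 1:
                        dst.append(slice(0, n - 1))
                        src.append(slice(1, 2 * n - 2, 2))
                    else:
                        dst.append(slice(1, n))
                        src.append(slice(1, 2 * n - 2, 2))
                g[tuple(dst)] = self.conductance[tuple(src)]
                out[tuple(int(x) for x in d)] = g
            self._offset_cond = out
        return self._offset_cond


def build_graph(
    geom: CellGeometry, conduction_map: frozenset = DEFAULT_CONDUCTION
) -> ReservoirGraph:
    """Build the reservoir tensor over a cell geometry.

    Occupancy is set for every voxel whose label conducts; signal and
    memory fields start at zero.
    """
    occupied = np.isin(geom.labels, [int(c) for c in conduction_map])
    doubled = tuple(2 * s - 1 for s in occupied.shape)
    occupancy = np.zeros(doubled, dtype=np.uint8)
    occupancy[::2, ::2, ::2] = occupied
    return ReservoirGraph(
        geom=geom,
        conduction_map=frozenset(conduction_map),
        occupied=occupied,
        occupancy=occupancy,
        I=np.zeros(occupied.shape),
        S=np.zeros(occupied.shape),
    )


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Underlying normal (mu, sigma) matching a log-normal mean and sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def assign_conductance(
    graph: ReservoirGraph, mean: float = 0.1, sd: float = 0.5, seed: int = 0
) -> ReservoirGraph:
    """Draw i.i.d. log-normal conductances for every edge-storage cell.

    ``mean`` and ``sd`` are the log-normal distribution's own mean and
    standard deviation; the underlying normal parameters come from the
    standard moment-matching formulas.  One value per storage cell, so
    crossing diagonals that share a cell share its conductance.
    """
    if mean <= 0 or sd <= 0:
        raise ConfigurationError("conductance mean and sd must be positive")
    mu, sigma = lognormal_params(mean, sd)
    rng = np.random.default_rng(seed)
    values = rng.lognormal(mu, sigma, size=graph.occupancy.shape)
    values[::2, ::2, ::2] = 0.0  # vertex cells store no conductance
    graph.conductance = values
    graph.conductance_seed = seed
    graph._offset_cond = None
    return graph


def r_ball(graph: ReservoirGraph, vertex: tuple[int, int, int]):
    """Iterate ``(neighbor_vertex, conductance)`` over occupied neighbors.

    ``vertex`` is an even index triple of the doubled tensor (the 5x5x5
    R-ball is centered on a vertex cell only).  The window clips at tensor
    boundaries; conductance for (v, w) equals that for (w, v) because both
    read the shared midpoint cell.
    """
    v = np.asarray(vertex, dtype=np.int64)
    if v.shape != (3,) or np.any(v % 2):
        raise ValueError(f"R-ball must be centered on an even index triple, got {vertex}")
    shape = np.asarray(graph.occupancy.shape)
    if np.any(v < 0) or np.any(v >= shape):
        raise ValueError(f"vertex {vertex} outside tensor of shape {tuple(shape)}")
    for d in _NEIGHBOR_OFFSETS:
        w = v + 2 * d
        if np.any(w < 0) or np.any(w >= shape):
            continue
        if not graph.occupancy[tuple(w)]:
            continue
        g = graph.conductance[tuple(v + d)] if graph.conductance is not None else None
        yield tuple(int(x) for x in w), g


@dataclass
class RBall:
    """A 5x5x5 window of the doubled tensor around one vertex.

    Even cells at Chebyshev offset 2 are the (at most 26) nearest-neighbor
    vertices; odd cells are the intervening edge-storage cells.  The window
    is a clipped view, not a copy.
    """

    center: tuple[int, int, int]
    window: np.ndarray
    lo: tuple[int, int, int]

    @classmethod
    def around(cls, graph: ReservoirGraph, vertex: tuple[int, int, int]) -> "RBall":
        v = np.asarray(vertex)
        if np.any(v % 2):
            raise ValueError("R-ball must be centered on an even index triple")
        lo = np.maximum(v - 2, 0)
        hi = np.minimum(v + 3, np.asarray(graph.occupancy.shape))
        window = graph.occupancy[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        return cls(tuple(int(x) for x in v), window, tuple(int(x) for x in lo))
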