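"""Potential fields, Huygens-style front propagation, currents and memory.

An environmental perturbation of charge amplitude δq at the peripheral
cytoplasm creates a screened-Coulomb (Debye–Hückel) potential landscape

    V_i = Σ_s δq_s · exp(-r_is / λ) / r_is

with λ the Debye length and r_is the Euclidean distance (μm) between
vertex i and source vertex s.  Information spreads as a discrete wavefront:
every informed voxel informs all of its occupied 26-neighbors at the next
step (one voxel per step), so the saturated informed set is exactly the
BFS-reachable set from the sources — connectivity, not the potential,
decides percolation.  The potential decides magnitudes: an informed vertex
aggregates Ohmic current from its informed neighbors at higher potential
(Kirchhoff summation), and each vertex keeps a memory state

    S_t = β·S_{t-1} + (1-β)·tanh(I_t),   S_0 = 0,

a bounded exponential moving average of its squashed current.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation

from .geometry import (
    _NEIGHBOR_OFFSETS,
    CellGeometry,
    ConfigurationError,
    Region,
    co_surface_mask,
    region_vertices,
)
from .reservoir import ReservoirGraph

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class NoSignalError(RuntimeError):
    """No signal reached the organelle: the geometry does not percolate."""


@dataclass
class SourceConfig:
    """Charge sources on the peripheral-cytoplasm shell.

    ``kind`` is ``"point"`` (a single PC voxel; by convention the one on
    the +x axis) or ``"spherical"`` (every PC voxel).  ``charge`` is the
    unitless per-vertex charge δq.
    """

    kind: str
    vertices: np.ndarray  # (m, 3) voxel index triples
    charge: float = 1.0

    def __post_init__(self):
        self.vertices = np.atleast_2d(np.asarray(self.vertices))
        if self.kind == "point" and len(self.vertices) != 1:
            raise ConfigurationError("point source must have exactly one vertex")
        if len(self.vertices) == 0:
            raise ConfigurationError("source must have at least one vertex")


def point_source(geom: CellGeometry, charge: float = 1.0) -> SourceConfig:
    """The PC voxel where the +x axis pierces the peripheral shell."""
    c = geom.center
    line = geom.labels[:, c, c]
    candidates = np.flatnonzero(line == Region.PC)
    if candidates.size == 0:
        raise ConfigurationError("no PC voxel on the +x axis")
    i = int(candidates.max())
    return SourceConfig("point", np.array([[i, c, c]]), charge)


def spherical_source(geom: CellGeometry, charge: float = 1.0) -> SourceConfig:
    """All PC-shell voxels as sources."""
    return SourceConfig("spherical", region_vertices(geom, Region.PC), charge)


def make_source(geom: CellGeometry, kind: str, charge: float = 1.0) -> SourceConfig:
    if kind == "point":
        return point_source(geom, charge)
    if kind == "spherical":
        return spherical_source(geom, charge)
    raise ConfigurationError(f"unknown source kind: {kind!r}")


@dataclass
class PotentialField:
    """Screened-Coulomb vertex potentials (unitless) on the voxel grid."""

    V: np.ndarray
    debye_length: float


def compute_potential(
    graph: ReservoirGraph,
    source: SourceConfig,
    debye_length: float = 1.0,
    charge: float | None = None,
) -> PotentialField:
    """Superpose exp(-kr)/r contributions of every source vertex.

    Potentials are evaluated at occupied voxels only (zero elsewhere).  The
    self-term of a source vertex uses ``r = voxel_size/2`` — the 1/r
    singularity is regularized at half a voxel so the source holds the
    field maximum.  The field is linear in the charge.
    """
    if debye_length <= 0:
        raise ConfigurationError("debye_length must be positive")
    geom = graph.geom
    q = source.charge if charge is None else charge
    V = np.zeros(graph.occupied.shape)
    if q == 0:
        return PotentialField(V, debye_length)
    vox = geom.voxel_size
    pts = np.argwhere(graph.occupied).astype(np.float64)  # (p, 3)
    src = source.vertices.astype(np.float64)  # (m, 3)
    k = 1.0 / debye_length
    r_min = vox / 2.0
    acc = np.zeros(len(pts))
    # chunk over sources to bound the (m, p) distance matrix
    for lo in range(0, len(src), 256):
        block = src[lo : lo + 256]
        diff = pts[None, :, :] - block[:, None, :]
        r = np.sqrt(np.einsum("spx,spx->sp", diff, diff)) * vox
        np.maximum(r, r_min, out=r)
        acc += (np.exp(-k * r) / r).sum(axis=0)
    V[graph.occupied] = q * acc
    return PotentialField(V, debye_length)


@dataclass
class PropagationState:
    """Huygens wavefront bookkeeping over discrete time."""

    t: int
    informed: np.ndarray   # (n,n,n) bool, non-decreasing in t
    frontier: np.ndarray   # vertices newly informed at step t
    co_surface: np.ndarray  # (n,n,n) bool mask
    co_arrival: int | None = None
    saturated: bool = False


def init_state(graph: ReservoirGraph, source: SourceConfig) -> PropagationState:
    informed = np.zeros(graph.occupied.shape, dtype=bool)
    informed[tuple(source.vertices.T)] = True
    informed &= graph.occupied
    if not informed.any():
        raise ConfigurationError("no source vertex is occupied")
    co_surf = co_surface_mask(graph.geom)
    state = PropagationState(0, informed, informed.copy(), co_surf)
    if bool((informed & co_surf).any()):
        state.co_arrival = 0
    return state


def step(graph: ReservoirGraph, state: PropagationState) -> PropagationState:
    """Advance the front one voxel: every informed voxel informs its
    occupied 26-neighbors.  Records first organelle-surface arrival and
    saturation (no newly informed vertices)."""
    grown = binary_dilation(state.informed, structure=_STRUCT26) & graph.occupied
    state.frontier = grown & ~state.informed
    state.informed = grown
    state.t += 1
    if not state.frontier.any():
        state.saturated = True
    elif state.co_arrival is None and bool((state.frontier & state.co_surface).any()):
        state.co_arrival = state.t
    return state


def propagate_to_saturation(
    graph: ReservoirGraph, source: SourceConfig, max_steps: int | None = None
) -> tuple[PropagationState, list[int]]:
    """Run the front until no new vertex is informed.

    Returns the final state and the per-step informed counts.  The guard
    ``max_steps`` (default 4x grid side) only matters for pathological
    occupancy patterns; the front otherwise saturates in at most
    ``#occupied`` steps.
    """
    if max_steps is None:
        max_steps = 4 * graph.n
    state = init_state(graph, source)
    counts = [int(state.informed.sum())]
    while not state.saturated and state.t < max_steps:
        step(graph, state)
        counts.append(int(state.informed.sum()))
    return state, counts


def reachable_set(graph: ReservoirGraph, source: SourceConfig) -> np.ndarray:
    """BFS-reachable occupied voxels from the sources (26-connectivity).

    Independent oracle for the saturated informed set; uses connected-
    component labeling rather than the stepping engine.
    """
    from scipy.ndimage import label

    lab, _ = label(graph.occupied, structure=_STRUCT26)
    src_labels = np.unique(lab[tuple(source.vertices.T)])
    src_labels = src_labels[src_labels > 0]
    return np.isin(lab, src_labels) & graph.occupied


def compute_signal(
    graph: ReservoirGraph,
    state: PropagationState,
    field: PotentialField,
    gate_downhill: bool = True,
) -> np.ndarray:
    """Aggregate incoming Ohmic current at every informed vertex.

    ``I_i = Σ_{n ∈ NN_i, informed, V_n > V_i} G_in (V_n − V_i)`` — current
    is received from uphill neighbors only (flow runs from higher to lower
    potential); currents aggregate at crossover points per Kirchhoff's
    current law.  Uninformed vertices keep I = 0.  With
    ``gate_downhill=False`` all informed-neighbor contributions are summed
    regardless of sign (exploration mode).
    """
    shape = graph.occupied.shape
    V = field.V
    act = state.informed & graph.occupied
    I = np.zeros(shape)
    cond = graph.offset_conductance()
    for d, g in cond.items():
        src = tuple(slice(max(x, 0), n - max(-x, 0)) for x, n in zip(d, shape))
        dst = tuple(slice(max(-x, 0), n - max(x, 0)) for x, n in zip(d, shape))
        dv = np.zeros(shape)
        pair_ok = np.zeros(shape, dtype=bool)
        dv[dst] = V[src] - V[dst]
        pair_ok[dst] = act[src]
        contrib = g * dv
        if gate_downhill:
            contrib = np.where(dv > 0, contrib, 0.0)
        I += np.where(pair_ok, contrib, 0.0)
    I[~act] = 0.0
    graph.I = I
    return I


def update_memory(graph: ReservoirGraph, I: np.ndarray, beta: float) -> np.ndarray:
    """EMA memory update S ← β·S + (1−β)·tanh(I) on occupied vertices.

    β in the open interval (0, 1): β=0 would mean no memory, β=1 no
    learning, so the endpoints are rejected.  No bias correction is
    applied to the early-time transient.
    """
    if not (0.0 < beta < 1.0):
        raise ConfigurationError(f"beta must lie strictly in (0, 1), got {beta}")
    S = graph.S
    upd = beta * S + (1.0 - beta) * np.tanh(I)
    S[graph.occupied] = upd[graph.occupied]
    return S


@dataclass
class Trajectory:
    """Per-step record of one driven reservoir run."""

    informed_counts: list[int]
    co_states: np.ndarray          # (steps, m) CO-surface memory snapshots
    co_vertices: np.ndarray        # (m, 3) canonical CO-surface order
    co_arrival: int | None         # δt: first organelle-surface arrival
    saturation_step: int | None
    n_inputs: int
    mean_abs_I: list[float] = field(default_factory=list)
    mean_S: list[float] = field(default_factory=list)

    @property
    def delta_t(self) -> int | None:
        return self.co_arrival

    def feature_matrix(self) -> np.ndarray:
        """δt-aligned readout features: row t is S at reservoir step t+δt."""
        if self.co_arrival is None:
            raise NoSignalError("no signal reached organelle")
        dt = self.co_arrival
        return self.co_states[dt : dt + self.n_inputs]


def run_sequence(
    graph: ReservoirGraph,
    source: SourceConfig,
    inputs: np.ndarray,
    beta: float = 0.5,
    debye_length: float = 1.0,
    gate_downhill: bool = True,
    require_percolation: bool = False,
) -> Trajectory:
    """Drive the reservoir with a time series of perturbation amplitudes.

    Per input sample: set all source charges to δq_t, recompute the
    potential (adiabatic: the field permeates instantly relative to the
    perturbation timescale), advance the front one voxel, aggregate
    currents over informed vertices, update memory, and record the
    organelle-surface memory snapshot.  The informed set persists across
    samples.

    The readout delay δt is the front's first organelle arrival, computed
    from the first sample's front and held fixed.  So that ``S^{t+δt}``
    exists for every input sample — sequences may be shorter than δt — the
    input is extended by holding its last value for δt extra steps.

    The potential is linear in charge, so the unit-charge field is computed
    once and scaled by δq_t each step.
    """
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim != 1:
        raise ConfigurationError("inputs must be a 1-D time series")
    co_verts = region_vertices_co_surface(graph.geom)
    graph.S = np.zeros(graph.occupied.shape)
    graph.I = np.zeros(graph.occupied.shape)
    if inputs.size == 0:
        return Trajectory([], np.zeros((0, len(co_verts))), co_verts, None, None, 0)

    # delay: pure-connectivity front run (charge-independent)
    probe, _ = propagate_to_saturation(graph, source)
    delta_t = probe.co_arrival
    if require_percolation and delta_t is None:
        raise NoSignalError("no signal reached organelle: geometry does not percolate")
    pad = delta_t if delta_t is not None else 0
    seq = np.concatenate([inputs, np.full(pad, inputs[-1])])

    unit = compute_potential(graph, source, debye_length, charge=1.0)
    state = init_state(graph, source)
    co_idx = tuple(co_verts.T)
    counts, co_states, mean_abs_I, mean_S = [], [], [], []
    occ = graph.occupied
    n_occ = max(int(occ.sum()), 1)
    # After saturation the informed set is fixed, so by linearity of the
    # potential and Ohmic currents in the charge, I(q) = |q| x one of two
    # cached unit patterns (uphill relations flip with the drive's sign).
    cached: tuple[np.ndarray, np.ndarray] | None = None
    for q in seq:
        step(graph, state)
        if state.saturated and cached is None:
            pos = compute_signal(graph, state, PotentialField(unit.V, debye_length),
                                 gate_downhill=gate_downhill).copy()
            neg = compute_signal(graph, state, PotentialField(-unit.V, debye_length),
                                 gate_downhill=gate_downhill).copy()
            cached = (pos, neg)
        if cached is not None:
            I = q * cached[0] if q >= 0 else -q * cached[1]
            graph.I = I
        else:
            fld = PotentialField(q * unit.V, debye_length)
            I = compute_signal(graph, state, fld, gate_downhill=gate_downhill)
        S = update_memory(graph, I, beta)
        counts.append(int(state.informed.sum()))
        co_states.append(S[co_idx].copy())
        mean_abs_I.append(float(np.abs(I[occ]).mean()))
        mean_S.append(float(S[occ].mean()))
    sat = next((i + 1 for i, c in enumerate(counts[1:]) if c == counts[i]), None)
    return Trajectory(
        informed_counts=counts,
        co_states=np.asarray(co_states),
        co_vertices=co_verts,
        co_arrival=state.co_arrival if state.co_arrival is not None else delta_t,
        saturation_step=sat,
        n_inputs=len(inputs),
        mean_abs_I=mean_abs_I,
        mean_S=mean_S,
    )


def region_vertices_co_surface(geom: CellGeometry) -> np.ndarray:
    from .geometry import CO_SURFACE

    return region_vertices(geom, CO_SURFACE)


def time_step_duration(voxel_size_um: float, signal_speed_m_s: float) -> float:
    """Physical duration (seconds) of one simulation step.

    One step moves the front one voxel, so Δt = voxel_size / signal speed;
    at 0.5 μm voxels and ion-flow speeds of 1–10 m/s this is 0.05–0.5 μs.
    """
    if voxel_size_um <= 0 or signal_speed_m_s <= 0:
        raise ConfigurationError("voxel size and signal speed must be positive")
    return voxel_size_um * 1e-6 / signal_speed_m_s
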