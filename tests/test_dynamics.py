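"""Potential fields, front propagation, currents and memory updates."""

import numpy as np
import pytest

from cellreservoir.dynamics import (
    NoSignalError,
    PotentialField,
    SourceConfig,
    compute_potential,
    compute_signal,
    init_state,
    make_source,
    point_source,
    propagate_to_saturation,
    reachable_set,
    run_sequence,
    spherical_source,
    step,
    time_step_duration,
    update_memory,
)
from cellreservoir.fixtures import make_fixture
from cellreservoir.geometry import CellGeometry, ConfigurationError, Region
from cellreservoir.reservoir import build_graph

from conftest import small_random_graph


def line_graph(length=5, conductances=None):
    """A 1-D conducting chain embedded in a (length x 3 x 3) label grid."""
    labels = np.full((length, 3, 3), Region.CYTO, dtype=np.uint8)
    labels[:, 1, 1] = Region.CS
    geom = CellGeometry(1.0, float(length), float(length) - 0.5, 1.0, labels)
    graph = build_graph(geom, frozenset({Region.CS}))
    side_x = 2 * length - 1
    graph.conductance = np.zeros((side_x, 5, 5))
    for i in range(length - 1):
        g = 1.0 if conductances is None else conductances[i]
        graph.conductance[2 * i + 1, 2, 2] = g
    return graph


def manual_field(graph, values):
    V = np.zeros_like(graph.I)
    V[:, 1, 1] = values
    return PotentialField(V, 1.0)


def all_informed(graph):
    state = init_state(
        graph, SourceConfig("point", np.argwhere(graph.occupied)[:1])
    )
    state.informed = graph.occupied.copy()
    return state


class TestPotential:
    def test_closed_form_single_source(self, small_cell):
        from cellreservoir.geometry import generate_cytoskeleton

        generate_cytoskeleton(small_cell, 1.0, 0)  # conducting everywhere inside
        graph = build_graph(small_cell)
        src = point_source(small_cell)
        field = compute_potential(graph, src, debye_length=1.0)
        i, j, k = src.vertices[0]
        # one voxel (1 μm) inward along -x: contribution e^-1/1
        assert field.V[i - 1, j, k] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_superposition(self, small_cell):
        graph = build_graph(small_cell)
        pc = np.argwhere(small_cell.labels == Region.PC)
        a = SourceConfig("point", pc[:1])
        b = SourceConfig("point", pc[-1:])
        both = SourceConfig("spherical", np.vstack([pc[:1], pc[-1:]]))
        Va = compute_potential(graph, a).V
        Vb = compute_potential(graph, b).V
        Vab = compute_potential(graph, both).V
        occ = graph.occupied
        assert np.allclose(Vab[occ], (Va + Vb)[occ], rtol=1e-12, atol=0)

    def test_source_holds_field_maximum(self, small_cell):
        graph = build_graph(small_cell)
        src = point_source(small_cell)
        field = compute_potential(graph, src)
        assert field.V.argmax() == np.ravel_multi_index(
            tuple(src.vertices[0]), field.V.shape
        )

    def test_potential_decreases_with_distance(self):
        graph = line_graph(8)
        src = SourceConfig("point", np.array([[0, 1, 1]]))
        V = compute_potential(graph, src).V[:, 1, 1]
        assert (np.diff(V) < 0).all()

    def test_linear_in_charge_and_zero_charge(self, small_cell):
        graph = build_graph(small_cell)
        src = point_source(small_cell, charge=2.0)
        V2 = compute_potential(graph, src).V
        V1 = compute_potential(graph, src, charge=1.0).V
        assert np.allclose(V2, 2 * V1, rtol=1e-12)
        assert compute_potential(graph, src, charge=0.0).V.max() == 0.0

    def test_spherical_aggregate_exceeds_point(self, small_cell):
        graph = build_graph(small_cell)
        Vp = compute_potential(graph, point_source(small_cell)).V
        Vs = compute_potential(graph, spherical_source(small_cell)).V
        occ = graph.occupied
        assert Vs[occ].sum() > Vp[occ].sum()


class TestFront:
    def test_chain_informs_one_voxel_per_step(self):
        graph = line_graph(6)
        state = init_state(graph, SourceConfig("point", np.array([[0, 1, 1]])))
        for expected_front in range(1, 6):
            step(graph, state)
            assert graph.occupied[expected_front, 1, 1]
            assert state.informed[: expected_front + 1, 1, 1].all()
            assert not state.informed[expected_front + 1 :, 1, 1].any()

    def test_disconnected_cluster_never_informed(self):
        geom, graph = make_fixture("tiny-nonpercolating")
        state, _ = propagate_to_saturation(graph, spherical_source(geom))
        assert state.saturated
        assert state.co_arrival is None

    def test_chain_fixture_arrival_is_length_plus_one(self):
        geom, graph = make_fixture("chain")
        for source in (point_source(geom), spherical_source(geom)):
            state, _ = propagate_to_saturation(graph, source)
            assert state.co_arrival == geom.chain_length + 1

    def test_informed_counts_monotone_until_saturation(self):
        for seed in range(5):
            graph = small_random_graph(seed)
            _, counts = propagate_to_saturation(
                graph, spherical_source(graph.geom)
            )
            diffs = np.diff(counts)
            assert (diffs >= 0).all()
            assert (diffs[:-1] > 0).all()  # strictly growing before saturation

    def test_saturated_set_equals_bfs_reachability(self):
        for seed in range(20):
            graph = small_random_graph(seed, cs_fraction=0.15 + 0.01 * seed)
            src = spherical_source(graph.geom)
            state, _ = propagate_to_saturation(graph, src)
            assert np.array_equal(state.informed, reachable_set(graph, src))

    def test_arrival_independent_of_charge(self, small_cell):
        from cellreservoir.geometry import generate_cytoskeleton

        generate_cytoskeleton(small_cell, 0.3, 2)
        graph = build_graph(small_cell)
        arrivals = []
        for charge in (1.0, 100.0):
            state, _ = propagate_to_saturation(
                graph, spherical_source(small_cell, charge)
            )
            arrivals.append(state.co_arrival)
        assert arrivals[0] == arrivals[1]

    def test_spherical_saturates_faster_than_point(self, reference_graph):
        geom = reference_graph.geom
        _, c_sph = propagate_to_saturation(reference_graph, spherical_source(geom))
        _, c_pt = propagate_to_saturation(reference_graph, point_source(geom))
        assert len(c_sph) < len(c_pt)


class TestSignal:
    def test_single_edge_downhill_current(self):
        graph = line_graph(2, conductances=[2.0])
        state = all_informed(graph)
        I = compute_signal(graph, state, manual_field(graph, [1.0, 0.5]))
        assert I[1, 1, 1] == pytest.approx(1.0)   # receives 2.0 * 0.5
        assert I[0, 1, 1] == 0.0                  # uphill vertex receives nothing

    def test_equal_potentials_no_current(self):
        graph = line_graph(2)
        state = all_informed(graph)
        I = compute_signal(graph, state, manual_field(graph, [0.7, 0.7]))
        assert not I.any()

    def test_junction_kirchhoff_sum(self):
        # A -- M -- B collinear: M receives from both uphill ends
        graph = line_graph(3, conductances=[1.0, 1.0])
        state = all_informed(graph)
        I = compute_signal(graph, state, manual_field(graph, [0.8, 0.5, 0.7]))
        assert I[1, 1, 1] == pytest.approx(0.3 + 0.2)

    def test_uninformed_vertices_stay_silent(self):
        graph = line_graph(3)
        state = init_state(graph, SourceConfig("point", np.array([[0, 1, 1]])))
        I = compute_signal(graph, state, manual_field(graph, [1.0, 0.5, 0.2]))
        assert not I.any()  # only the source is informed; it has no uphill peer

    def test_current_linear_in_potential_scale(self):
        graph = line_graph(4, conductances=[0.5, 1.5, 2.5])
        state = all_informed(graph)
        v = np.array([1.0, 0.4, 0.9, 0.1])
        I1 = compute_signal(graph, state, manual_field(graph, v))
        I2 = compute_signal(graph, state, manual_field(graph, 2 * v))
        assert np.allclose(I2, 2 * I1, rtol=1e-12)


class TestMemory:
    def test_zero_current_keeps_zero_state(self):
        graph = line_graph(3)
        S = update_memory(graph, np.zeros_like(graph.S), beta=0.5)
        assert not S.any()

    def test_small_beta_approaches_tanh(self):
        graph = line_graph(3)
        I = np.full_like(graph.S, 0.8)
        S = update_memory(graph, I, beta=1e-9)
        occ = graph.occupied
        assert np.allclose(S[occ], np.tanh(0.8), rtol=1e-6)

    def test_constant_current_converges_geometrically(self):
        graph = line_graph(3)
        beta, I_val = 0.7, 1.3
        I = np.full_like(graph.S, I_val)
        for t in range(1, 30):
            update_memory(graph, I, beta)
            expected = (1 - beta**t) * np.tanh(I_val)
            assert graph.S[graph.occupied] == pytest.approx(expected, rel=1e-12)

    def test_memory_bounded_under_random_currents(self):
        rng = np.random.default_rng(0)
        graph = line_graph(4)
        for _ in range(200):
            I = rng.normal(0, 50, size=graph.S.shape)
            update_memory(graph, I, beta=0.9)
            assert (np.abs(graph.S) < 1).all()

    @pytest.mark.parametrize("beta", [0.0, 1.0, -0.1, 1.5])
    def test_beta_endpoints_rejected(self, beta):
        graph = line_graph(2)
        with pytest.raises(ConfigurationError):
            update_memory(graph, graph.I, beta)


class TestRunSequence:
    def test_zero_inputs_zero_trajectory(self, small_cell):
        from cellreservoir.geometry import generate_cytoskeleton
        from cellreservoir.reservoir import assign_conductance

        generate_cytoskeleton(small_cell, 0.3, 5)
        graph = assign_conductance(build_graph(small_cell), seed=6)
        traj = run_sequence(graph, spherical_source(small_cell), np.zeros(12))
        assert not traj.co_states.any()
        assert not graph.S.any()

    def test_empty_input_empty_trajectory(self, small_cell):
        graph = build_graph(small_cell)
        traj = run_sequence(graph, spherical_source(small_cell), np.array([]))
        assert traj.co_states.shape[0] == 0

    def test_feature_rows_match_input_count(self):
        _, graph = make_fixture("tiny-percolating", seed=1)
        traj = run_sequence(
            graph, spherical_source(graph.geom), np.cos(np.arange(30) / 3),
            require_percolation=True,
        )
        X = traj.feature_matrix()
        assert X.shape == (30, len(traj.co_vertices))
        assert (np.abs(X) < 1).all()

    def test_nonpercolating_raises_when_required(self):
        geom, graph = make_fixture("tiny-nonpercolating")
        with pytest.raises(NoSignalError):
            run_sequence(
                graph, spherical_source(geom), np.ones(5), require_percolation=True
            )

    def test_saturation_cache_matches_direct_computation(self):
        # the post-saturation linear-scaling shortcut must equal stepwise
        # recomputation of the gated Kirchhoff currents
        _, graph = make_fixture("tiny-percolating", seed=2)
        src = spherical_source(graph.geom)
        inputs = np.cos(np.arange(40) / 4.0)
        traj = run_sequence(graph, src, inputs, beta=0.5)

        # independent re-run: explicit per-step fields, no cache
        from cellreservoir.dynamics import compute_potential, init_state

        graph.S = np.zeros_like(graph.S)
        unit = compute_potential(graph, src, 1.0, charge=1.0)
        state = init_state(graph, src)
        probe, _ = propagate_to_saturation(graph, src)
        seq = np.concatenate([inputs, np.full(probe.co_arrival, inputs[-1])])
        states = []
        co_idx = tuple(traj.co_vertices.T)
        for q in seq:
            step(graph, state)
            I = compute_signal(graph, state, PotentialField(q * unit.V, 1.0))
            update_memory(graph, I, 0.5)
            states.append(graph.S[co_idx].copy())
        assert np.allclose(np.asarray(states), traj.co_states, rtol=1e-12, atol=1e-15)


class TestPhysicalMapping:
    @pytest.mark.parametrize(
        "voxel,speed,expected_us",
        [(0.5, 1.0, 0.5), (0.5, 10.0, 0.05), (1.0, 1.0, 1.0)],
    )
    def test_step_duration(self, voxel, speed, expected_us):
        assert time_step_duration(voxel, speed) * 1e6 == pytest.approx(expected_us)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ConfigurationError):
            time_step_duration(-0.5, 1.0)


class TestSources:
    def test_point_source_on_x_axis(self, small_cell):
        src = point_source(small_cell)
        i, j, k = src.vertices[0]
        c = small_cell.center
        assert (j, k) == (c, c) and i > c
        assert small_cell.labels[i, j, k] == Region.PC

    def test_spherical_source_covers_shell(self, small_cell):
        src = spherical_source(small_cell)
        assert len(src.vertices) == small_cell.counts()["PC"]

    def test_unknown_kind_rejected(self, small_cell):
        with pytest.raises(ConfigurationError):
            make_source(small_cell, "cubic")
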