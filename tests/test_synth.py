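"""Ground-truth generator: topologies, event dynamics, perturbations, rendering."""

import networkx as nx
import numpy as np
import pytest

import respnet
from respnet import synth
from respnet.traces import TraceSet


class TestGenerateNetwork:
    def test_ring_lattice_degrees(self):
        g = respnet.generate_network(
            respnet.NetworkSpec(n_cells=20, topology="ring_lattice", k=4))
        assert set(dict(g.degree()).values()) == {4}

    def test_small_world_without_rewiring_equals_lattice(self):
        lat = respnet.generate_network(
            respnet.NetworkSpec(n_cells=20, topology="ring_lattice", k=4, seed=7))
        sw = respnet.generate_network(
            respnet.NetworkSpec(n_cells=20, topology="small_world", k=4,
                                rewire_p=0.0, seed=7))
        assert set(lat.edges()) == set(sw.edges())

    def test_planted_clusters_crossing_edges_counted_bruteforce(self):
        spec = respnet.NetworkSpec(n_cells=40, topology="planted_clusters", k=4,
                                   n_clusters=2, inter_cluster_edges=1, seed=5)
        g = respnet.generate_network(spec)
        cluster = nx.get_node_attributes(g, "cluster")
        crossing = [e for e in g.edges() if cluster[e[0]] != cluster[e[1]]]
        assert len(crossing) == 1

    def test_degree_at_least_n_rejected(self):
        with pytest.raises(ValueError):
            respnet.generate_network(respnet.NetworkSpec(n_cells=10, k=10))

    def test_same_seed_same_graph(self):
        a = respnet.generate_network(respnet.NetworkSpec(seed=9))
        b = respnet.generate_network(respnet.NetworkSpec(seed=9))
        assert set(a.edges()) == set(b.edges())

    def test_no_self_loops_any_topology(self):
        for topo in synth.TOPOLOGIES:
            g = respnet.generate_network(
                respnet.NetworkSpec(n_cells=24, topology=topo, k=4,
                                    hub_fraction=0.2, seed=2))
            assert nx.number_of_selfloops(g) == 0


class TestSimulateRecording:
    def test_jitterless_pacemaker_event_count(self, noiseless_dynamics):
        """50 mHz for 60 s with a phase inside the first period gives 3 events."""
        dyn = noiseless_dynamics
        dyn.pacemaker_rate = 50.0
        dyn.pacemaker_fraction = 1.0
        dyn.duration = 60.0
        net = nx.empty_graph(2)
        rec = respnet.simulate_recording(net, dyn, seed=3)
        for ev in rec.truth_events:
            assert len(ev) == 3
            assert ev[0] < 20.0  # phase within one period
            np.testing.assert_allclose(np.diff(ev), 20.0)

    def test_decoupling_silences_followers(self):
        g = respnet.generate_network(respnet.NetworkSpec(n_cells=20, k=4, seed=1))
        dyn = respnet.DynamicsSpec(duration=200.0)
        rec = respnet.simulate_recording(
            g, dyn, [respnet.PerturbationSpec("decouple_all", onset=0.0)], seed=2)
        followers = ~rec.pacemaker_mask
        assert all(len(rec.truth_events[i]) == 0 for i in np.flatnonzero(followers))
        assert all(len(rec.truth_events[i]) > 0
                   for i in np.flatnonzero(rec.pacemaker_mask))

    def test_rate_scaling_halves_intervals(self):
        net = nx.empty_graph(4)
        dyn = respnet.DynamicsSpec(pacemaker_fraction=1.0, rate_jitter_cv=0.2,
                                   duration=2000.0, frame_interval=2.0)
        base = respnet.simulate_recording(net, dyn, seed=6)
        fast = respnet.simulate_recording(
            net, dyn, [respnet.PerturbationSpec("scale_rate", 2.0, 0.0)], seed=6)
        mean_base = np.mean([np.diff(t).mean() for t in base.truth_events])
        mean_fast = np.mean([np.diff(t).mean() for t in fast.truth_events])
        assert mean_fast == pytest.approx(mean_base / 2, rel=0.10)

    def test_events_within_recording(self, small_recording):
        dur = small_recording.traces.duration
        for ev in small_recording.truth_events:
            assert np.all((ev >= 0) & (ev <= dur))
            assert np.all(np.diff(ev) > 0)

    def test_determinism_bit_identical(self):
        g = respnet.generate_network(respnet.NetworkSpec(n_cells=15, k=4, seed=0))
        dyn = respnet.DynamicsSpec(duration=120.0)
        a = respnet.simulate_recording(g, dyn, seed=42)
        b = respnet.simulate_recording(g, dyn, seed=42)
        np.testing.assert_array_equal(a.traces.values, b.traces.values)
        assert all(np.array_equal(x, y)
                   for x, y in zip(a.truth_events, b.truth_events))

    def test_follower_event_count_monotone_in_transmission_prob(self):
        g = respnet.generate_network(respnet.NetworkSpec(n_cells=20, k=4, seed=8))
        dyn_lo = respnet.DynamicsSpec(transmission_prob=0.3, duration=300.0)
        counts = []
        for p in (0.3, 0.6, 0.9):
            dyn = respnet.DynamicsSpec(transmission_prob=p, duration=300.0)
            total = 0
            for seed in range(5):
                rec = respnet.simulate_recording(g, dyn, seed=seed)
                total += sum(len(rec.truth_events[i])
                             for i in np.flatnonzero(~rec.pacemaker_mask))
            counts.append(total)
        assert counts[0] <= counts[1] <= counts[2]

    def test_pacemaker_identity_invariant_to_perturbations(self):
        g = respnet.generate_network(respnet.NetworkSpec(n_cells=20, k=4, seed=8))
        dyn = respnet.DynamicsSpec(duration=120.0)
        a = respnet.simulate_recording(g, dyn, seed=5)
        b = respnet.simulate_recording(
            g, dyn, [respnet.PerturbationSpec("delete_edge_fraction", 0.5)], seed=5)
        np.testing.assert_array_equal(a.pacemaker_mask, b.pacemaker_mask)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            respnet.DynamicsSpec(duration=1.0, frame_interval=1.0).validate()


class TestRenderStack:
    def test_constant_trace_gives_identical_frames(self):
        ts = TraceSet(values=np.full((1, 5), 7.0), frame_interval=1.0)
        rec = synth.SimulatedRecording(traces=ts, truth_graph=nx.empty_graph(1),
                                       pacemaker_mask=np.array([True]),
                                       truth_events=[np.array([])])
        stack = respnet.render_stack(rec, positions=[[10.0, 10.0]], shape=(24, 24))
        assert np.allclose(stack, stack[0])

    def test_zero_cells_pure_background(self):
        ts = TraceSet(values=np.empty((0, 4)), frame_interval=1.0)
        rec = synth.SimulatedRecording(traces=ts, truth_graph=nx.empty_graph(0),
                                       pacemaker_mask=np.zeros(0, bool),
                                       truth_events=[])
        stack = respnet.render_stack(rec, positions=np.empty((0, 2)),
                                     shape=(16, 16), background=3.0)
        assert np.allclose(stack, 3.0)

    def test_footprint_intensity_tracks_trace(self, noiseless_dynamics):
        dyn = noiseless_dynamics
        dyn.pacemaker_fraction = 1.0
        net = nx.empty_graph(1)
        rec = respnet.simulate_recording(net, dyn, seed=1)
        pos = np.array([[16.0, 16.0]])
        stack = respnet.render_stack(rec, pos, radii=2.0, shape=(32, 32))
        inside = stack[:, 13:20, 13:20].mean(axis=(1, 2))
        r = np.corrcoef(inside, rec.traces.values[0])[0, 1]
        assert r > 0.99

    def test_out_of_bounds_position_rejected(self):
        ts = TraceSet(values=np.ones((1, 3)), frame_interval=1.0)
        rec = synth.SimulatedRecording(traces=ts, truth_graph=nx.empty_graph(1),
                                       pacemaker_mask=np.array([False]),
                                       truth_events=[np.array([])])
        with pytest.raises(ValueError):
            respnet.render_stack(rec, positions=[[99.0, 5.0]], shape=(16, 16))
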