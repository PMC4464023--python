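import networkx as nx
import numpy as np
import pytest

import protnet as pn
from protnet.simulation import diffusion_phase, initialize

from conftest import chi2_class_test


def small_config(**overrides):
    base = dict(L=8, occupancy=0.2, p_on=0.7, p_off=0.02, n_steps=100,
                seed=0, record_every=50)
    base.update(overrides)
    return pn.SimulationConfig(**base)


class TestInitialize:
    def test_counts_and_equal_allocation(self):
        net = pn.InteractionNetwork([f"S{i}" for i in range(10)],
                                    [(i, (i + 1) % 10) for i in range(10)])
        cfg = pn.SimulationConfig(L=10, occupancy=0.5, n_steps=0, seed=1)
        state = initialize(net, cfg)
        assert state.n_instances == 500
        counts = {}
        for sp in state.species_of:
            counts[sp] = counts.get(sp, 0) + 1
        assert all(c == 50 for c in counts.values())
        state.check_invariants()

    def test_remainder_spread_over_distinct_species(self, triangle):
        cfg = pn.SimulationConfig(L=4, occupancy=0.5, n_steps=0, seed=2)
        state = initialize(triangle, cfg)           # 32 instances, 3 species
        counts = sorted(state.initial_species_counts.values())
        assert sum(counts) == 32
        assert counts == [10, 11, 11]   # remainder spread over 2 distinct species

    def test_zero_occupancy_is_an_error(self, triangle):
        with pytest.raises(ValueError):
            initialize(triangle, pn.SimulationConfig(L=4, occupancy=0.0,
                                                     n_steps=0))

    def test_fewer_instances_than_species_is_an_error(self):
        net = pn.InteractionNetwork([f"S{i}" for i in range(30)],
                                    [(0, i) for i in range(1, 30)])
        with pytest.raises(ValueError):
            initialize(net, pn.SimulationConfig(L=2, occupancy=0.5, n_steps=0))

    def test_no_initial_bonds(self, clique_ring):
        state = initialize(clique_ring, small_config())
        assert all(b == -1 for row in state.bonds for b in row)
        assert len(state.complexes) == state.n_instances


class TestStepInvariants:
    def test_p_on_zero_keeps_everything_monomeric(self, clique_ring):
        trace = pn.run(clique_ring, small_config(p_on=0.0, n_steps=60))
        for _, comps in trace.snapshots:
            assert all(len(c) == 1 for c in comps)

    def test_determinism_same_seed_same_trace(self, clique_ring):
        t1 = pn.run(clique_ring, small_config(n_steps=80, seed=5))
        t2 = pn.run(clique_ring, small_config(n_steps=80, seed=5))
        assert t1.snapshots == t2.snapshots
        t3 = pn.run(clique_ring, small_config(n_steps=80, seed=6))
        assert t3.snapshots != t1.snapshots

    def test_conservation_exclusion_and_bond_legality(self, clique_ring):
        state = initialize(clique_ring, small_config(p_off=0.05, seed=3))
        for k in range(600):
            pn.step(state)
            if (k + 1) % 150 == 0:
                state.check_invariants()

    def test_closed_boundary_keeps_coordinates_in_bounds(self, clique_ring):
        cfg = small_config(boundary="closed", seed=4)
        state = initialize(clique_ring, cfg)
        for k in range(300):
            pn.step(state)
        state.check_invariants()
        L = cfg.L
        for i in range(state.n_instances):
            assert 0 <= state.px[i] < L and 0 <= state.py[i] < L \
                and 0 <= state.pz[i] < L

    def test_diameter_move_law_also_satisfies_invariants(self, clique_ring):
        state = initialize(clique_ring, small_config(move_law="diameter",
                                                     seed=7))
        for _ in range(200):
            pn.step(state)
        state.check_invariants()

    def test_random_visit_order_also_satisfies_invariants(self, clique_ring):
        state = initialize(clique_ring, small_config(visit_order="random",
                                                     seed=8))
        for _ in range(200):
            pn.step(state)
        state.check_invariants()


class TestDiffusion:
    def test_single_monomer_moves_uniformly_from_open_site(self, dimer_net):
        # closed 3x3x3 lattice, instance at the centre: all six directions
        # are available and must be chosen uniformly
        cfg = pn.SimulationConfig(L=3, occupancy=1 / 27, p_on=0.0,
                                  n_steps=0, seed=0, boundary="closed")
        state = pn.SimulationState(dimer_net, cfg)
        i = state.add_instance(0, 1, 1, 1)
        counts = {}
        for _ in range(6000):
            before = (state.px[i], state.py[i], state.pz[i])
            diffusion_phase(state)
            after = (state.px[i], state.py[i], state.pz[i])
            delta = tuple(a - b for a, b in zip(after, before))
            counts[delta] = counts.get(delta, 0) + 1
            # teleport back to the centre for the next trial
            state.grid[state.site[i]] = -1
            state.px[i], state.py[i], state.pz[i] = 1, 1, 1
            state.site[i] = state._site_of_coords(1, 1, 1)
            state.grid[state.site[i]] = i
        assert set(counts) == {(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                               (0, 0, 1), (0, 0, -1)}
        probs = {d: 1 / 6 for d in counts}
        assert chi2_class_test(counts, probs) > 0.01

    def test_equal_mass_push_displaces_the_blocked_monomer(self, dimer_net):
        # two monomers head-on in a 1D corridor of a closed lattice
        cfg = pn.SimulationConfig(L=4, occupancy=0.1, p_on=0.0, n_steps=0,
                                  seed=0, boundary="closed")
        state = pn.SimulationState(dimer_net, cfg)
        a = state.add_instance(0, 1, 0, 0)
        b = state.add_instance(1, 2, 0, 0)
        assert state._try_translate(state.comp_of[a], 0)   # push along +x
        assert (state.px[a], state.px[b]) == (2, 3)

    def test_rigid_dimer_preserves_bond_geometry(self, dimer_net):
        cfg = pn.SimulationConfig(L=6, occupancy=2 / 216, p_on=1.0, p_off=0.0,
                                  n_steps=0, seed=1)
        state = pn.SimulationState(dimer_net, cfg)
        a = state.add_instance(0, 2, 2, 2)
        b = state.add_instance(1, 3, 2, 2)
        state.initial_species_counts = {0: 1, 1: 1}
        for k in range(2000):
            pn.step(state)
            if k == 0:
                assert state.comp_of[a] == state.comp_of[b], "dimer must form"
            rel = (state.px[b] - state.px[a], state.py[b] - state.py[a],
                   state.pz[b] - state.pz[a])
            assert sorted(map(abs, rel)) == [0, 0, 1], "face adjacency lost"
        state.check_invariants()

    def test_absorbing_dimer_with_zero_off_rate(self, dimer_net):
        cfg = pn.SimulationConfig(L=4, occupancy=2 / 64, p_on=0.7, p_off=0.0,
                                  n_steps=0, seed=2)
        state = initialize(dimer_net, cfg)
        bonded_steps = 0
        for _ in range(400):
            pn.step(state)
            if len(state.complexes) == 1:
                bonded_steps += 1
        assert len(state.complexes) == 1
        assert bonded_steps > 200


class TestComplexes:
    def test_all_monomer_state(self, clique_ring):
        state = initialize(clique_ring, small_config(seed=9))
        recs = pn.complexes(state)
        assert len(recs) == state.n_instances
        assert all(r.mass == 1 and r.diameter == 1 for r in recs)

    def test_components_match_networkx_oracle(self, clique_ring):
        state = initialize(clique_ring, small_config(p_off=0.02, seed=10))
        for _ in range(300):
            pn.step(state)
        g = nx.Graph()
        g.add_nodes_from(range(state.n_instances))
        for i in range(state.n_instances):
            for j in state.bonds[i]:
                if j >= 0:
                    g.add_edge(i, j)
        oracle = {frozenset(c) for c in nx.connected_components(g)}
        ours = {frozenset(r.members) for r in pn.complexes(state)}
        assert ours == oracle

    def test_species_sets_and_diameters_consistent(self, clique_ring):
        state = initialize(clique_ring, small_config(seed=11))
        for _ in range(200):
            pn.step(state)
        for r in pn.complexes(state):
            assert len(r.species_set) == r.mass        # species uniqueness
            xs = [state.px[m] for m in r.members]
            ys = [state.py[m] for m in r.members]
            zs = [state.pz[m] for m in r.members]
            cheb = max(max(xs) - min(xs), max(ys) - min(ys), max(zs) - min(zs))
            assert r.diameter == cheb + 1


class TestKineticResponse:
    def test_mean_complex_mass_decreases_with_off_rate(self):
        net = pn.make_fixture_network("ring_of_cliques", 3, clique_size=5)
        means = []
        for p_off in (0.002, 0.02, 0.2):
            vals = []
            for seed in range(3):
                cfg = pn.SimulationConfig(L=8, occupancy=0.2, p_on=0.7,
                                          p_off=p_off, n_steps=2000,
                                          seed=seed, record_every=2000)
                state = pn.run(net, cfg).final_state
                vals.append(np.mean([c.mass for c in state.complexes.values()]))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestTraceIO:
    def test_snapshot_files_round_trip(self, tmp_path, clique_ring):
        trace = pn.run(clique_ring, small_config(n_steps=60, seed=12),
                       out_dir=tmp_path)
        files = sorted(tmp_path.glob("snapshot_*.tsv"))
        assert len(files) == len(trace.snapshots)
        cell = pn.read_complex_list(files[-1])
        expected = sorted(trace.final_compositions(),
                          key=lambda c: (-len(c), sorted(c)))
        assert sorted(cell, key=lambda c: (-len(c), sorted(c))) == expected
        series_dir = pn.ssi_timeseries(tmp_path)
        series_mem = pn.ssi_timeseries(trace)
        assert np.allclose(series_dir["ssi"], series_mem["ssi"])

    def test_zero_steps_trace_contains_initial_snapshot_only(self, clique_ring):
        trace = pn.run(clique_ring, small_config(n_steps=0))
        assert len(trace.snapshots) == 1
        assert trace.snapshots[0][0] == 0
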