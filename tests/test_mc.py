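"""Counterion-bridging Monte Carlo: sampling correctness and mechanism."""

import itertools
import math

import numpy as np
import pytest

from ionbridge.mc import McState, ToyParams, cluster_partition, run_mc


class TestMoves:
    def test_flat_landscape_translation_acceptance_is_unity(self):
        # with every energy term zero and no ions there are no tethers and
        # no hard core: every translation is accepted
        p = ToyParams(n_particles=8, ion_count=0, bridge_energy_kT=0.0,
                      bind_energy_kT=0.0, binding_entropy_kT=0.0,
                      charge_penalty_kT=0.0, hard_core_nm=0.0,
                      n_sweeps=50, seed=1)
        tr = run_mc(p)
        assert tr.acceptance["particle"] == 1.0

    def test_flat_landscape_with_ions_only_tethers_reject(self):
        # zero energies but ions present: bind/unbind toggles are free, so
        # transient tethers reject a minority of translations
        p = ToyParams(n_particles=8, ion_count=10, bridge_energy_kT=0.0,
                      bind_energy_kT=0.0, binding_entropy_kT=0.0,
                      charge_penalty_kT=0.0, hard_core_nm=0.0,
                      n_sweeps=50, seed=1)
        tr = run_mc(p)
        assert tr.acceptance["particle"] > 0.5
        assert tr.acceptance["ion"] > 0.5

    def test_no_ions_no_binding_gas_of_singletons(self):
        p = ToyParams(n_particles=10, ion_count=0, n_sweeps=30, seed=2)
        tr = run_mc(p)
        assert np.all(tr.n_bound == 0)
        assert np.all(tr.largest_cluster == 1)
        assert np.all(tr.mean_cluster == 1.0)

    def test_fixed_seed_bit_reproducible(self):
        p = ToyParams(n_particles=6, ion_count=30, n_sweeps=40, seed=9)
        a, b = run_mc(p), run_mc(p)
        np.testing.assert_array_equal(a.energy, b.energy)
        np.testing.assert_array_equal(a.n_bound, b.n_bound)
        np.testing.assert_array_equal(a.final_state.particles,
                                      b.final_state.particles)

    def test_energy_bookkeeping_consistent(self):
        p = ToyParams(n_particles=8, ion_count=40, n_sweeps=60, seed=3)
        tr = run_mc(p)
        assert tr.energy_bookkeeping_error < 1e-9


def _frozen_two_particle_state(params):
    """Two particles and one ion at fixed, mutually in-range positions."""
    rng = np.random.default_rng(0)
    st = McState(params, rng)
    st.particles[:] = [[9.5, 10.0], [10.5, 10.0]]
    st.ions[:] = [[10.0, 10.0]]
    return st


class TestBoltzmannEnumeration:
    def test_two_particle_one_ion_matches_exact_weights(self):
        # frozen positions: the reachable states are the occupancy subsets
        # of the 2*S sites with size <= max_sites_per_ion
        S, cap = 3, 2
        params = ToyParams(n_particles=2, sites_per_particle=S, ion_count=1,
                           box_nm=(20.0, 20.0), bridge_energy_kT=-1.0,
                           bind_energy_kT=-0.5, binding_entropy_kT=0.3,
                           charge_penalty_kT=0.05, max_sites_per_ion=cap,
                           particle_step_nm=0.0, ion_step_nm=0.0,
                           n_sweeps=12000, seed=17)

        def energy(subset):
            # independent reconstruction of the model energy: bonds,
            # bridge reward, and the neighbour charge product (the two
            # particles sit 1 nm apart, inside the repulsion range)
            n = len(subset)
            parts = {s // S for s in subset}
            e = (params.bind_energy_kT + params.binding_entropy_kT) * n
            share = 2.0 / len(parts) if parts else 0.0
            qa = (share if 0 in parts else 0.0) - S
            qb = (share if 1 in parts else 0.0) - S
            if len(parts) == 2:
                e += params.bridge_energy_kT
            e += params.charge_penalty_kT * qa * qb
            return e

        states = [s for k in range(cap + 1)
                  for s in itertools.combinations(range(2 * S), k)]
        weights = np.array([math.exp(-energy(set(s))) for s in states])
        probs = weights / weights.sum()
        # exact marginal distribution of the number of bound sites
        exact_n = np.zeros(cap + 1)
        for s, pr in zip(states, probs):
            exact_n[len(s)] += pr

        st = _frozen_two_particle_state(params)
        tr = run_mc(params, record_every=3, initial_state=st)
        burn = len(tr.n_bound) // 5
        samples = tr.n_bound[burn:]
        n_samp = len(samples)
        for k in range(cap + 1):
            observed = np.mean(samples == k)
            se = np.sqrt(max(exact_n[k] * (1 - exact_n[k]), 1e-12) / n_samp)
            # thinned but still weakly correlated samples: allow 3 SE with
            # a mild effective-sample-size inflation
            assert abs(observed - exact_n[k]) < 3 * se * 2.0, \
                f"occupancy {k}: observed {observed:.4f} vs exact {exact_n[k]:.4f}"

    def test_bridging_probability_matches_enumeration(self):
        S, cap = 3, 2
        params = ToyParams(n_particles=2, sites_per_particle=S, ion_count=1,
                           box_nm=(20.0, 20.0), bridge_energy_kT=-2.0,
                           bind_energy_kT=-0.5, binding_entropy_kT=0.0,
                           charge_penalty_kT=0.0, max_sites_per_ion=cap,
                           particle_step_nm=0.0, ion_step_nm=0.0,
                           n_sweeps=12000, seed=23)
        b = params.bind_energy_kT + params.binding_entropy_kT
        states = [s for k in range(cap + 1)
                  for s in itertools.combinations(range(2 * S), k)]

        def energy(sub):
            bridging = len({x // S for x in sub}) == 2
            return b * len(sub) + (params.bridge_energy_kT if bridging else 0.0)

        w = np.array([math.exp(-energy(s)) for s in states])
        p_bridge = sum(wi for s, wi in zip(states, w)
                       if len({x // S for x in s}) == 2) / w.sum()
        st = _frozen_two_particle_state(params)
        tr = run_mc(params, record_every=3, initial_state=st)
        burn = len(tr.largest_cluster) // 5
        observed = np.mean(tr.largest_cluster[burn:] == 2)
        n_samp = len(tr.largest_cluster) - burn
        se = np.sqrt(p_bridge * (1 - p_bridge) / n_samp)
        assert abs(observed - p_bridge) < 3 * se * 2.0


class TestClusterPartition:
    def _state_with_bonds(self, n_particles, bonds, sites_per_particle=4):
        params = ToyParams(n_particles=n_particles,
                           sites_per_particle=sites_per_particle,
                           ion_count=len(bonds) or 1, n_sweeps=1, seed=0)
        st = McState(params, np.random.default_rng(0))
        next_site = {p: 0 for p in range(n_particles)}
        for ion, parts in enumerate(bonds):
            for p in parts:
                st._bind(ion, p * sites_per_particle + next_site[p])
                next_site[p] += 1
        return st

    def test_no_bonds_all_singletons(self):
        st = self._state_with_bonds(5, [])
        parts, sizes = cluster_partition(st)
        assert sizes == [1, 1, 1, 1, 1]

    def test_single_bridge_joins_pair(self):
        st = self._state_with_bonds(4, [(0, 1)])
        _, sizes = cluster_partition(st)
        assert sizes == [2, 1, 1]

    @pytest.mark.parametrize("seed", range(5))
    def test_random_bridge_graphs_match_networkx(self, seed):
        import networkx as nx

        rng = np.random.default_rng(seed)
        n = 12
        bonds = []
        for _ in range(rng.integers(0, 10)):
            k = int(rng.integers(1, 4))
            bonds.append(tuple(rng.choice(n, size=k, replace=False)))
        st = self._state_with_bonds(n, bonds)
        parts, _ = cluster_partition(st)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for parts_of_ion in bonds:
            for a, bnd in zip(parts_of_ion, parts_of_ion[1:]):
                g.add_edge(a, bnd)
        expected = sorted(sorted(c) for c in nx.connected_components(g))
        assert sorted(sorted(c) for c in parts) == expected

    def test_direct_contact_rule_links_neighbours(self):
        params = ToyParams(n_particles=2, ion_count=1, n_sweeps=1, seed=0)
        st = McState(params, np.random.default_rng(0))
        st.particles[:] = [[5.0, 5.0], [5.3, 5.0]]
        _, sizes = cluster_partition(st, contact_rule="bridge+contact",
                                     direct_contact_nm=0.5)
        assert sizes == [2]


class TestEnergyModel:
    def test_energy_recomputable_from_state(self):
        p = ToyParams(n_particles=10, ion_count=60, n_sweeps=25, seed=5)
        tr = run_mc(p)
        st = tr.final_state
        assert st.energy == pytest.approx(st.total_energy(), abs=1e-9)

    def test_neighbour_repulsion_tracks_bound_charge(self):
        # two bare particles in range: repulsion lam * (-S)^2; binding an
        # ion to one reduces |q| and therefore the product
        p = ToyParams(n_particles=2, sites_per_particle=6, ion_count=1,
                      charge_penalty_kT=1.0, n_sweeps=1, seed=0)
        st = McState(p, np.random.default_rng(0))
        st.particles[:] = [[5.0, 5.0], [5.5, 5.0]]
        st.ions[:] = [[5.25, 5.0]]
        assert st._pair_repulsion() == pytest.approx(36.0)
        st._bind(0, 0)                      # single bond on particle 0
        assert st._pair_repulsion() == pytest.approx((-4.0) * (-6.0))
        st._bind(0, 6)                      # now bridging: +1 share each
        assert st._pair_repulsion() == pytest.approx((-5.0) * (-5.0))
        np.testing.assert_allclose(st.q, [-5.0, -5.0])

    def test_charge_shares_consistent_after_random_toggles(self):
        p = ToyParams(n_particles=6, ion_count=30, n_sweeps=30, seed=12)
        tr = run_mc(p)
        st = tr.final_state
        S = p.sites_per_particle
        expected = np.full(p.n_particles, -float(S))
        for ion in st.bound_ions:
            k = len(st.ion_particles[ion])
            for part in st.ion_particles[ion]:
                expected[part] += 2.0 / k
        np.testing.assert_allclose(st.q, expected, atol=1e-9)
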