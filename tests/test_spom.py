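"""SPOM engine: rates, stepping, path-blocked dispersal, exact-oracle checks."""

import numpy as np
import pytest

import streamspom as sp
from streamspom.activation import ActivationSeries
from streamspom.errors import ContractViolationError, ParameterError, SizeError
from streamspom.spom import (
    KERNEL_CUTOFF_DELTAS,
    DispersalCache,
    active_path_distance_matrix,
    exact_occupancy_distribution,
    simulate_spom_ensemble,
)

from conftest import make_chain


class TestTraits:
    def test_positivity_enforced(self):
        with pytest.raises(ParameterError):
            sp.SpeciesTraits(c=-1, e=1, delta=100)

    def test_soft_bounds_warn(self):
        with pytest.warns(UserWarning):
            sp.SpeciesTraits(c=1e3, e=1.0, delta=100.0)

    def test_focal_species_scales_with_nnd(self):
        tr = sp.SpeciesTraits.focal(nnd=120.0)
        assert (tr.c, tr.e, tr.delta) == (0.015, 20.0, 480.0)


class TestSuitability:
    def test_wet_bed_area_and_dry_zero(self, chain3):
        S = sp.suitability(chain3, np.array([1, 0, 1]))
        np.testing.assert_allclose(S, [200.0, 0.0, 200.0])  # 100 m × 2 m


class TestDistances:
    def test_self_distance_zero_and_chain_additivity(self, chain3):
        d = sp.active_path_distances(chain3, {0, 1, 2})
        assert d[(1, 1)] == 0.0
        assert d[(0, 2)] == pytest.approx(200.0)
        assert d[(2, 0)] == pytest.approx(200.0)

    def test_dry_intermediate_node_blocks_path(self, chain3):
        d = sp.active_path_distances(chain3, {0, 2}, sources={0})
        assert (0, 2) not in d
        assert d[(0, 0)] == 0.0

    def test_inactive_source_rejected(self, chain3):
        with pytest.raises(ContractViolationError):
            sp.active_path_distances(chain3, {0, 1}, sources={2})

    def test_matrix_matches_networkx_on_random_active_sets(self, small_net):
        nx = pytest.importorskip("networkx")
        g = nx.Graph()
        for (i, j), w in zip(small_net.edges, small_net.edge_lengths):
            g.add_edge(int(i), int(j), weight=float(w))
        rng = np.random.default_rng(8)
        for _ in range(5):
            mask = rng.random(small_net.n_nodes) < 0.6
            D = active_path_distance_matrix(small_net, mask)
            sub = g.subgraph(np.flatnonzero(mask).tolist())
            lengths = dict(nx.all_pairs_dijkstra_path_length(sub))
            for i in np.flatnonzero(mask):
                for j in np.flatnonzero(mask):
                    expected = lengths.get(int(i), {}).get(int(j), np.inf)
                    assert D[i, j] == pytest.approx(expected)

    def test_cache_agrees_with_direct_computation(self, small_net):
        order_desc = sp.proxy_ranking(small_net, "twi").order_desc
        cache = DispersalCache(small_net, order_desc)
        for size in (1, 7, 25, small_net.n_nodes):
            idx = cache.active_nodes(size)
            mask = np.zeros(small_net.n_nodes, bool)
            mask[idx] = True
            D_direct = active_path_distance_matrix(small_net, mask)
            np.testing.assert_allclose(cache.distances(size), D_direct[np.ix_(idx, idx)])


class TestRates:
    def test_no_occupied_nodes_no_colonization(self, chain3):
        D = active_path_distance_matrix(chain3, np.ones(3, bool))
        S = sp.suitability(chain3, np.ones(3))
        C = sp.colonization_rates(chain3, S, np.zeros(3), sp.SpeciesTraits(0.015, 20, 400), D)
        np.testing.assert_array_equal(C, 0.0)

    def test_hand_evaluated_pair_rate(self):
        # two nodes 100 m apart, δ=400 m, S_source=500 m², c=0.015:
        # C = 0.015·exp(−0.25)·500 ≈ 5.841 1/d
        net = make_chain(2, spacing=100.0, width=5.0)
        D = active_path_distance_matrix(net, np.ones(2, bool))
        S = sp.suitability(net, np.ones(2))
        traits = sp.SpeciesTraits(c=0.015, e=20.0, delta=400.0)
        C = sp.colonization_rates(net, S, np.array([0, 1]), traits, D)
        assert C[0] == pytest.approx(0.015 * np.exp(-0.25) * 500.0, rel=1e-12)
        assert C[1] == 0.0  # occupied node contributes no rate to itself

    def test_infinite_dispersal_limit_sums_suitability(self, small_net):
        D = active_path_distance_matrix(small_net, np.ones(small_net.n_nodes, bool))
        S = sp.suitability(small_net, np.ones(small_net.n_nodes))
        w = np.ones(small_net.n_nodes)
        traits = sp.SpeciesTraits(c=2.0, e=1.0, delta=1e15)
        C = sp.colonization_rates(small_net, S, w, traits, D)
        expected = 2.0 * (S.sum() - S)
        np.testing.assert_allclose(C, expected, rtol=1e-9)

    def test_extinction_hand_value_dry_rule_and_limit(self):
        traits = sp.SpeciesTraits(c=0.015, e=20.0, delta=400.0)
        E, phi = sp.extinction_rates(np.array([500.0, 0.0, 1e12]), traits)
        assert E[0] == pytest.approx(0.04)
        assert phi[0] == pytest.approx(1 - np.exp(-0.04))  # ≈ 0.0392
        assert phi[1] == 1.0 and np.isinf(E[1])
        assert phi[2] == pytest.approx(0.0, abs=1e-10)

    def test_kernel_cutoff_truncation_error_negligible(self):
        # long chain so some pairs sit beyond 23·δ
        net = make_chain(120, spacing=100.0)
        traits = sp.SpeciesTraits(c=0.015, e=20.0, delta=450.0)
        D = active_path_distance_matrix(net, np.ones(net.n_nodes, bool))
        S = sp.suitability(net, np.ones(net.n_nodes))
        w = np.ones(net.n_nodes)
        C_full = sp.colonization_rates(net, S, w, traits, D)
        cache = DispersalCache(net, sp.proxy_ranking(net, "area").order_desc)
        K = cache.kernel(net.n_nodes, traits.delta)
        idx = cache.active_nodes(net.n_nodes)
        C_trunc = np.empty_like(C_full)
        C_trunc[idx] = traits.c * ((w[idx] * S[idx]) @ K)
        assert D.max() > KERNEL_CUTOFF_DELTAS * traits.delta  # truncation engaged
        np.testing.assert_allclose(C_trunc, C_full, rtol=1e-9)


class TestStepping:
    def test_forced_transitions(self):
        rng = np.random.default_rng(0)
        w = sp.spom_step(np.array([0, 1, 0]), phi_c=np.array([1.0, 0, 0]),
                         phi_e=np.array([0, 1.0, 0]), rng=rng)
        np.testing.assert_array_equal(w, [True, False, False])

    def test_whole_network_extinction_is_absorbing(self, chain3):
        acts = ActivationSeries.from_matrix(chain3, np.ones((30, 3), bool))
        traits = sp.SpeciesTraits(c=0.015, e=20.0, delta=400.0)
        traj = sp.simulate_spom(chain3, acts, traits, w0=np.zeros(3, bool), seed=1)
        assert not traj.w.any()

    def test_same_seed_identical_trajectory(self, small_net):
        field = sp.calibrate_thresholds(
            small_net, sp.proxy_ranking(small_net, "area"), sp.ClimateParams.preset("intermediate")
        )
        rain = sp.effective_rainfall(sp.ClimateParams.preset("intermediate"), 120, seed=2)
        q = sp.simulate_discharge(rain, q0="stationary", seed=3)
        acts = sp.activate(q, field)
        traits = sp.SpeciesTraits.focal(small_net.nnd)
        t1 = sp.simulate_spom(small_net, acts, traits, seed=77)
        t2 = sp.simulate_spom(small_net, acts, traits, seed=77)
        np.testing.assert_array_equal(t1.w, t2.w)

    def test_occupied_nodes_are_never_dry(self, small_net):
        field = sp.calibrate_thresholds(
            small_net, sp.proxy_ranking(small_net, "random"), sp.ClimateParams.preset("dry")
        )
        rain = sp.effective_rainfall(sp.ClimateParams.preset("dry"), 200, seed=6)
        q = sp.simulate_discharge(rain, q0="stationary", seed=7)
        acts = sp.activate(q, field)
        traj = sp.simulate_spom(small_net, acts, sp.SpeciesTraits.focal(small_net.nnd), seed=8)
        assert not np.any(traj.w & ~acts.X)

    def test_initial_occupancy_on_dry_node_rejected(self, chain3):
        X = np.ones((5, 3), bool)
        X[0, 1] = False
        acts = ActivationSeries.from_matrix(chain3, X)
        with pytest.raises(ContractViolationError):
            sp.simulate_spom(chain3, acts, sp.SpeciesTraits(0.015, 20, 400),
                             w0=np.array([1, 1, 0], bool))

    def test_near_zero_extinction_keeps_static_network_full(self, small_net):
        acts = ActivationSeries.from_matrix(
            small_net, np.ones((100, small_net.n_nodes), bool)
        )
        with pytest.warns(UserWarning):
            traits = sp.SpeciesTraits(c=0.015, e=1e-9, delta=500.0)
        traj = sp.simulate_spom(small_net, acts, traits,
                                w0=np.ones(small_net.n_nodes, bool), seed=4)
        assert traj.w.all()

    def test_monotone_response_to_traits(self, chain3):
        # paired-seed comparison on a static 3-node chain
        acts = ActivationSeries.from_matrix(chain3, np.ones((60, 3), bool))

        def mean_occ(c, e, seed=123):
            w = simulate_spom_ensemble(
                chain3, acts, sp.SpeciesTraits(c=c, e=e, delta=300.0), n_rep=400, seed=seed
            )
            return w.mean()

        assert mean_occ(c=0.02, e=50.0) >= mean_occ(c=0.002, e=50.0)
        assert mean_occ(c=0.005, e=20.0) >= mean_occ(c=0.005, e=200.0)


class TestExactOracle:
    def test_single_node_geometric_survival(self):
        net = make_chain(2, width=5.0)
        X = np.zeros((8, 2), bool)
        X[:, 0] = True  # only the outlet is ever wet
        acts = ActivationSeries.from_matrix(net, X)
        traits = sp.SpeciesTraits(c=1e-4, e=20.0, delta=100.0)
        _, marg = exact_occupancy_distribution(net, acts, traits, w0=np.array([1, 0], bool))
        p_stay = np.exp(-20.0 / 500.0)  # S = 100 m × 5 m
        np.testing.assert_allclose(marg[:, 0], p_stay ** np.arange(8), rtol=1e-12)
        np.testing.assert_array_equal(marg[:, 1], 0.0)

    def test_state_distribution_normalised(self, chain3):
        X = np.ones((10, 3), bool)
        X[4:6, 1] = False
        acts = ActivationSeries.from_matrix(chain3, X)
        probs, _ = exact_occupancy_distribution(chain3, acts, sp.SpeciesTraits(0.002, 20, 300))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_size_limit(self):
        net = make_chain(13)
        acts = ActivationSeries.from_matrix(net, np.ones((2, 13), bool))
        with pytest.raises(SizeError):
            exact_occupancy_distribution(net, acts, sp.SpeciesTraits(0.01, 20, 300))

    def test_loop_engine_marginals_match_oracle(self, chain3):
        # the scalar engine must follow the same law as the exact propagator
        X = np.ones((15, 3), bool)
        X[6:9, 2] = False
        acts = ActivationSeries.from_matrix(chain3, X)
        traits = sp.SpeciesTraits(c=0.002, e=20.0, delta=300.0)
        _, marg = exact_occupancy_distribution(chain3, acts, traits)
        n_rep = 3000
        fin = np.array(
            [sp.simulate_spom(chain3, acts, traits, seed=5000 + i).w[-1] for i in range(n_rep)]
        )
        se = np.sqrt(marg[-1] * (1 - marg[-1]) / n_rep)
        assert np.all(np.abs(fin.mean(0) - marg[-1]) < 4 * se + 1e-12)
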