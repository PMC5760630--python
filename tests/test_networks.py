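import numpy as np
import pytest

from prcnet import (
    DirectedNetwork,
    F_closed_form,
    count_inferable_links,
    expected_inferable_fraction,
    generate_random_network,
    generate_scale_free_network,
    inferability_IF,
    inferability_IF_star,
)
from prcnet.networks import NetworkError, PerturbedSet

from conftest import random_weighted_net


class TestDirectedNetwork:
    def test_rejects_self_loops_and_bidirectional_pairs(self):
        with pytest.raises(NetworkError):
            DirectedNetwork(nodes=[1], edges={(1, 1)})
        with pytest.raises(NetworkError):
            DirectedNetwork(nodes=[1, 2], edges={(1, 2), (2, 1)})

    def test_invert_swaps_directions(self, chain):
        inv = chain.invert()
        assert inv.edges == {(2, 1), (3, 2)}
        assert inv.invert().edges == chain.edges


class TestCounting:
    def test_two_perturbed_triangle_fully_inferable_refined(self, fully_inferable_triangle):
        count, flags = count_inferable_links(fully_inferable_triangle, {1, 2}, "refined")
        assert count == 3 and all(flags.values())
        # motif mode alone cannot rescue the link between the two perturbed nodes
        count_m, _ = count_inferable_links(fully_inferable_triangle, {1, 2}, "motif")
        assert count_m == 2

    def test_perturbed_out_hub_non_inferable(self, out_hub):
        for mode in ("motif", "refined"):
            count, _ = count_inferable_links(out_hub, {0}, mode)
            assert count == 0

    def test_all_perturbed_all_inferable(self):
        net, _ = random_weighted_net(12, seed=0)
        count, _ = count_inferable_links(net, set(net.nodes), "motif")
        assert count == net.n_edges

    @pytest.mark.parametrize("seed", range(4))
    def test_motif_flags_never_exceed_refined(self, seed):
        net, rng = random_weighted_net(12, seed=seed)
        perturbed = {v for v in net.nodes if rng.random() < 0.5}
        cm, fm = count_inferable_links(net, perturbed, "motif")
        cr, fr = count_inferable_links(net, perturbed, "refined")
        assert cm <= cr
        assert all(fr[e] for e in fm if fm[e])  # refined keeps every motif flag


class TestExpectedFraction:
    @pytest.mark.parametrize("q,expected", [(0.3, 0.3), (0.5, 0.5), (0.9, 0.9)])
    def test_single_edge_F_equals_q(self, single_edge, q, expected):
        assert F_closed_form(single_edge, q) == pytest.approx(expected)
        assert expected_inferable_fraction(
            single_edge, q, "exhaustive", "motif"
        ) == pytest.approx(expected)

    def test_chain_exhaustive_value(self, chain):
        # per-link inferability probabilities q^2(2-q) and q, averaged
        assert expected_inferable_fraction(chain, 0.5, "exhaustive", "motif") == pytest.approx(0.4375)
        assert F_closed_form(chain, 0.5) == pytest.approx(0.4375)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_closed_form_equals_exhaustive_motif_expectation(self, seed):
        net, _ = random_weighted_net(8, seed=seed)
        for q in (0.2, 0.5, 0.8):
            exact = expected_inferable_fraction(net, q, "exhaustive", "motif")
            assert F_closed_form(net, q) == pytest.approx(exact, abs=1e-12)

    def test_monte_carlo_within_three_standard_errors(self, chain):
        draws = 10_000
        est = expected_inferable_fraction(chain, 0.5, draws, "motif", seed=3)
        se = np.sqrt(0.4375 * (1 - 0.4375) / draws) * 1.5  # conservative per-draw spread
        assert abs(est - 0.4375) < 3 * se + 0.01

    def test_extremes_and_errors(self, chain):
        assert expected_inferable_fraction(chain, 1.0, "exhaustive") == 1.0
        assert expected_inferable_fraction(chain, 0.0, "exhaustive") == 0.0
        with pytest.raises(NetworkError):
            expected_inferable_fraction(chain, 1.5, 10)
        with pytest.raises(NetworkError):
            expected_inferable_fraction(
                DirectedNetwork(nodes=[1], edges=set()), 0.5, 10
            )

    def test_F_monotone_in_q(self):
        net, _ = random_weighted_net(20, seed=5)
        qs = np.linspace(0, 1, 21)
        F = [F_closed_form(net, q) for q in qs]
        assert F[0] == 0.0 and F[-1] == pytest.approx(1.0)
        assert all(b >= a - 1e-12 for a, b in zip(F, F[1:]))


class TestGenerators:
    def test_scale_free_determinism_and_constraints(self):
        a = generate_scale_free_network(100, 2.5, 2.0, "outgoing", seed=9)
        b = generate_scale_free_network(100, 2.5, 2.0, "outgoing", seed=9)
        assert a.edges == b.edges
        assert a.n_edges == 200  # realised mean degree exactly as requested
        for s, t in a.edges:
            assert s != t and (t, s) not in a.edges

    def test_incoming_hub_mode_is_inversion(self):
        out = generate_scale_free_network(50, 2.5, 2.0, "outgoing", seed=4)
        inc = generate_scale_free_network(50, 2.5, 2.0, "incoming", seed=4)
        assert inc.edges == {(t, s) for s, t in out.edges}

    def test_tiny_network_edge_budget(self):
        net = generate_scale_free_network(3, 2.5, 0.67, "outgoing", seed=0)
        assert net.n_edges <= 2

    def test_generator_errors(self):
        with pytest.raises(NetworkError):
            generate_scale_free_network(2, 2.5, 1.0)
        with pytest.raises(NetworkError):
            generate_scale_free_network(10, 0.9, 2.0)
        with pytest.raises(NetworkError):
            generate_scale_free_network(10, 2.5, 20.0)
        with pytest.raises(NetworkError):
            generate_random_network(10, 9.5)

    def test_random_network_mean_degree(self):
        counts = [generate_random_network(100, 3.0, seed=s).n_edges for s in range(10)]
        assert np.mean(counts) == pytest.approx(300, abs=1)  # deterministic edge budget
        net = generate_random_network(2, 0.5, seed=1)
        assert net.n_edges <= 1

    def test_outgoing_hubs_have_high_out_degree(self):
        net = generate_scale_free_network(200, 2.5, 3.0, "outgoing", seed=2)
        od = np.array(sorted(net.out_degree().values()))
        id_ = np.array(sorted(
            np.bincount([t for _, t in net.edges], minlength=200)
        ))
        assert od.max() > id_.max()  # hubs send, not receive


class TestInferabilityMeasures:
    def test_single_edge_IF_and_star(self, single_edge):
        curve = inferability_IF(single_edge)
        assert curve.I_F == pytest.approx(0.5, abs=1e-4)
        assert inferability_IF_star(single_edge) == pytest.approx(0.5, abs=1e-4)

    def test_identical_outdegree_star_matches_direct_formula(self):
        # directed 4-cycle: every node has out-degree 1, no shared targets
        net = DirectedNetwork(nodes=[0, 1, 2, 3], edges={(0, 1), (1, 2), (2, 3), (3, 0)})
        # k=1, l=1, m=0 for each edge: F*(q) = q^2 + (1-q) q^2
        qs = np.linspace(0, 1, 101)
        expected = np.trapezoid(qs**2 + (1 - qs) * qs**2, qs)
        assert inferability_IF_star(net) == pytest.approx(expected, abs=1e-6)
        assert inferability_IF(net).I_F == pytest.approx(expected, abs=1e-6)

    def test_hub_direction_ordering(self):
        sf = generate_scale_free_network(150, 2.5, 3.0, "outgoing", seed=8)
        rnd = generate_random_network(150, 3.0, seed=8)
        IF_out = inferability_IF(sf).I_F
        IF_in = inferability_IF(sf.invert()).I_F
        IF_rand = inferability_IF(rnd).I_F
        assert IF_out < IF_rand < IF_in

    def test_IF_decreases_with_mean_degree(self):
        vals = [
            inferability_IF(generate_scale_free_network(150, 2.5, k, "outgoing", seed=3)).I_F
            for k in (2.0, 3.0, 5.0)
        ]
        assert vals[0] > vals[1] > vals[2]

    def test_size_invariance(self):
        small = inferability_IF(generate_scale_free_network(150, 2.5, 3.0, "outgoing", seed=1)).I_F
        large = inferability_IF(generate_scale_free_network(300, 2.5, 3.0, "outgoing", seed=1)).I_F
        assert abs(small - large) < 0.05

    def test_grid_validation(self, single_edge):
        with pytest.raises(NetworkError):
            inferability_IF(single_edge, np.array([0.0, 0.5, 0.5, 1.0]))

    def test_monte_carlo_estimator_agrees_with_closed_form(self, chain):
        mc = inferability_IF(chain, np.linspace(0, 1, 21), "monte_carlo", n_draws=400, seed=0)
        cf = inferability_IF(chain, np.linspace(0, 1, 21), "closed_form")
        assert mc.I_F == pytest.approx(cf.I_F, abs=0.02)


def test_edge_list_round_trip(tmp_path, chain):
    net = DirectedNetwork(
        nodes=["a", "b", "c"], edges={("a", "b"), ("b", "c")},
        weights={("a", "b"): 1.5, ("b", "c"): -0.5},
    )
    path = tmp_path / "net.tsv"
    net.to_tsv(path)
    back = DirectedNetwork.from_tsv(path)
    assert back.edges == net.edges
    assert back.weights == net.weights
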