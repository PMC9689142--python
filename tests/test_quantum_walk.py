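import numpy as np
import pytest
from scipy.stats import spearmanr

from qwlink import (
    Network,
    QuantumWalkScorer,
    build_coin,
    build_evolution,
    build_operators,
    build_shift,
    evolve,
    initial_state,
    score_all,
    score_link,
)

from conftest import make_random_network
from oracles import literal_coin, literal_evolution, literal_shift

SQRT3 = np.sqrt(3.0)


class TestCoin:
    def test_triangle(self, triangle):
        expected = np.array([[4, 1, 1], [1, 4, 1], [1, 1, 4]], dtype=float)
        assert np.array_equal(build_coin(triangle), expected)

    def test_path(self, path3):
        expected = np.array([[2, -1, 2], [-1, 4, -1], [2, -1, 2]], dtype=float)
        assert np.array_equal(build_coin(path3), expected)

    def test_edgeless(self):
        net = Network(node_labels=[0, 1, 2], edges=set())
        assert np.array_equal(build_coin(net), np.zeros((3, 3)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_set_intersection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net = make_random_network(rng, 9, 0.4)
        assert np.allclose(build_coin(net), literal_coin(net), atol=1e-12)


class TestShift:
    def test_path_lower_block(self, path3):
        s = build_shift(path3)
        lower = s[3:, 3:]
        expected = np.array([[0, 1, 0], [0.5, 0, 0.5], [0, 1, 0]])
        assert np.allclose(lower, expected)
        assert np.array_equal(s[:3, :3], np.eye(3))
        assert np.all(s[:3, 3:] == 0) and np.all(s[3:, :3] == 0)

    def test_isolated_node_row_is_zero(self):
        net = Network(node_labels=[0, 1, 2], edges={(0, 1)})
        s = build_shift(net)
        assert np.all(s[3 + 2, :] == 0)

    def test_non_dangling_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        net = make_random_network(rng, 10, 0.3)
        s = build_shift(net)
        lower = s[10:, 10:]
        rowsum = lower.sum(axis=1)
        d = net.degrees
        assert np.allclose(rowsum[d > 0], 1.0)
        assert np.allclose(rowsum[d == 0], 0.0)


class TestEvolution:
    def test_block_structure(self, path3):
        coin = build_coin(path3)
        u = build_evolution(coin, build_shift(path3))
        assert np.allclose(u[:3, :3], coin)
        expected_lower = np.array([[-1, 4, -1], [2, -1, 2], [-1, 4, -1]], dtype=float)
        assert np.allclose(u[3:, 3:], expected_lower)
        assert np.all(u[:3, 3:] == 0) and np.all(u[3:, :3] == 0)

    def test_dimension_mismatch(self, path3, triangle):
        with pytest.raises(ValueError, match="dimension"):
            build_evolution(build_coin(path3), np.eye(4))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_literal_operator_construction(self, seed):
        """Block form equals the outer-product/Kronecker construction."""
        rng = np.random.default_rng(100 + seed)
        net = make_random_network(rng, int(rng.integers(2, 9)), 0.5)
        ops = build_operators(net)
        assert np.allclose(ops.shift, literal_shift(net), atol=1e-12)
        assert np.allclose(ops.evolution, literal_evolution(net), atol=1e-12)


class TestState:
    def test_initial_conventions(self):
        net = Network(node_labels=list(range(4)), edges={(0, 1)})
        st = initial_state(net)
        assert np.allclose(st.amplitudes, 0.5)
        st = initial_state(net, "inv_n")
        assert np.allclose(st.amplitudes, 0.25)
        with pytest.raises(ValueError):
            initial_state(net, "bogus")

    def test_single_node(self):
        net = Network(node_labels=[0], edges=set())
        st = initial_state(net)
        assert np.allclose(st.amplitudes, 1.0)

    def test_zero_steps_identity(self, path3):
        ops = build_operators(path3)
        st = initial_state(path3)
        out = evolve(ops, st, 0)
        assert np.array_equal(out.amplitudes, st.amplitudes)
        assert out.step == 0

    def test_two_step_path_amplitudes(self, path3):
        ops = build_operators(path3)
        st = evolve(ops, initial_state(path3), 2)
        assert np.allclose(st.psi0, np.array([10, 2, 10]) / SQRT3)
        assert np.allclose(st.psi1, np.array([8, 5, 8]) / SQRT3)

    def test_negative_steps(self, path3):
        ops = build_operators(path3)
        with pytest.raises(ValueError):
            evolve(ops, initial_state(path3), -1)

    @pytest.mark.parametrize("seed", range(5))
    def test_stepwise_equals_power(self, seed):
        rng = np.random.default_rng(seed)
        net = make_random_network(rng, 8, 0.4)
        ops = build_operators(net)
        st = initial_state(net)
        stepped = st
        for _ in range(4):
            stepped = evolve(ops, stepped, 1)
        direct = evolve(ops, st, 4)
        assert np.allclose(stepped.amplitudes, direct.amplitudes, rtol=1e-10)

    def test_amplitudes_stay_real(self):
        rng = np.random.default_rng(11)
        net = make_random_network(rng, 10, 0.3)
        st = evolve(build_operators(net), initial_state(net), 3)
        assert np.isrealobj(st.amplitudes)


class TestScoring:
    def test_worked_example_ordered(self, path3):
        ops = build_operators(path3)
        st = initial_state(path3)
        got = score_link(path3, ops, st, 0, 2, training_edge_count=2, steps=2)
        assert got == pytest.approx(9 / SQRT3, rel=1e-12)

    def test_zero_common_neighbours_scores_zero(self, path3):
        ops = build_operators(path3)
        st = initial_state(path3)
        assert score_link(path3, ops, st, 0, 1, training_edge_count=2) == 0.0

    def test_self_pair_rejected(self, path3):
        ops = build_operators(path3)
        st = initial_state(path3)
        with pytest.raises(ValueError):
            score_link(path3, ops, st, 1, 1, training_edge_count=2)

    def test_zero_steps_formula(self, triangle):
        """At t=0 the score is just the CN prefactor times 2α."""
        ops = build_operators(triangle)
        st = initial_state(triangle)
        got = score_link(triangle, ops, st, 0, 1, training_edge_count=3, steps=0)
        assert got == pytest.approx((1 / 3) * 2 / SQRT3)

    def test_score_all_sum_and_zero_pairs(self, path3):
        sm = score_all(path3, training_edge_count=2, symmetrization="sum")
        assert sm.scores[0, 2] == pytest.approx(18 / SQRT3, rel=1e-12)
        assert sm.scores[0, 1] == 0.0 and sm.scores[1, 2] == 0.0

    def test_mean_is_half_of_sum(self, karate):
        mean = score_all(karate, symmetrization="mean").scores
        total = score_all(karate, symmetrization="sum").scores
        assert np.allclose(total, 2 * mean)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_and_zero_support(self, seed):
        rng = np.random.default_rng(50 + seed)
        net = make_random_network(rng, 12, 0.3)
        if net.num_edges == 0:
            pytest.skip("edgeless draw")
        sm = score_all(net).scores
        assert np.allclose(sm, sm.T)
        assert np.all(np.diag(sm) == 0)
        cn = net.adjacency @ net.adjacency
        np.fill_diagonal(cn, 0)
        assert np.all(sm[cn == 0] == 0)

    def test_amplitude_convention_rescales_scores(self, karate):
        """1/N vs 1/√N amplitudes scale every score by 1/√N; ranks equal."""
        a = QuantumWalkScorer(amplitude_convention="inv_sqrt_n").fit(karate).scores_
        b = QuantumWalkScorer(amplitude_convention="inv_n").fit(karate).scores_
        n = karate.num_nodes
        assert np.allclose(b, a / np.sqrt(n))
        iu = np.triu_indices(n, k=1)
        rho, _ = spearmanr(a[iu], b[iu])
        assert rho == pytest.approx(1.0)

    def test_sklearn_params_roundtrip(self):
        sc = QuantumWalkScorer(steps=3, symmetrization="sum")
        params = sc.get_params()
        assert params["steps"] == 3
        sc2 = QuantumWalkScorer().set_params(**params)
        assert sc2.get_params() == params
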