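import numpy as np
import pytest

from predinet import (
    StimulusEnsemble,
    build_connectivity,
    condition,
    energy,
    feedforward_input,
    make_network,
    prune,
    sample_weights,
    simulate,
)
from predinet.errors import DimensionError, ParameterError


def loop_connectivity(weights):
    """Brute-force elementwise oracle for J = -(1/N) sum_k (w w^T + v v^T)."""
    N, P = weights.N, weights.P
    J = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            for k in range(P):
                J[i, j] -= (
                    weights.W[i, k] * weights.W[j, k] + weights.V[i, k] * weights.V[j, k]
                ) / N
    return J


def loop_feedforward(weights, stim):
    N, P = weights.N, weights.P
    out = np.zeros(N)
    for i in range(N):
        for k in range(P):
            out[i] += weights.W[i, k] * stim.x[k] + weights.V[i, k] * stim.y[k]
    return out


def loop_energy(net, r, stim):
    """Direct term-by-term summation of the objective."""
    N, P = net.N, net.P
    e = 0.0
    for k in range(P):
        xh = sum(net.weights.W[i, k] * r[i] for i in range(N)) / N
        yh = sum(net.weights.V[i, k] * r[i] for i in range(N)) / N
        e += (stim.x[k] - xh) ** 2 + (stim.y[k] - yh) ** 2
    for i in range(N):
        e += (r[i] + net.params.theta) ** 2 / (net.params.b * N)
    return e


class TestConnectivity:
    def test_matches_elementwise_oracle(self):
        w = sample_weights(50, 3, 0.5, seed=4)
        J = build_connectivity(w)
        assert np.allclose(J, loop_connectivity(w), atol=1e-12)

    def test_degenerate_fully_learned_pair_is_rank_one(self):
        w = sample_weights(80, 1, 1.0, seed=2)  # mu=1 => v == w exactly
        assert np.array_equal(w.W, w.V)
        J = build_connectivity(w)
        assert np.allclose(J, -2.0 / 80 * np.outer(w.W[:, 0], w.W[:, 0]))
        assert np.linalg.matrix_rank(J, tol=1e-10) == 1

    def test_symmetric_negative_semidefinite_low_rank(self):
        w = sample_weights(120, 4, 0.3, seed=5)
        J = build_connectivity(w)
        assert np.array_equal(J, J.T)
        eigs = np.linalg.eigvalsh(J)
        assert eigs.max() < 1e-10
        assert np.linalg.matrix_rank(J, tol=1e-8) <= 2 * 4


class TestFeedforward:
    def test_zero_when_absent(self, small_trained_net):
        stim = condition(2, "absent")
        assert not feedforward_input(small_trained_net.weights, stim).any()

    def test_single_pair_gives_weight_column(self):
        w = sample_weights(30, 3, 0.0, seed=1)
        IF = feedforward_input(w, condition(3, "x_only", pair=2))
        assert np.allclose(IF, w.W[:, 2])

    def test_matches_loop_oracle(self, rng):
        w = sample_weights(20, 4, 0.5, seed=8)
        stim = StimulusEnsemble(rng.uniform(0, 1, 4), rng.uniform(0, 1, 4))
        assert np.allclose(feedforward_input(w, stim), loop_feedforward(w, stim))

    def test_dimension_mismatch_raises(self):
        w = sample_weights(20, 4, 0.5, seed=8)
        with pytest.raises(DimensionError):
            feedforward_input(w, condition(3, "match"))


class TestEnergy:
    def test_all_zero_is_zero(self):
        net = make_network(40, 1, 0.5, b=2.0, seed=0)
        assert energy(net, np.zeros(40), condition(1, "absent")) == 0.0

    def test_silent_network_single_stimulus_costs_one(self):
        net = make_network(40, 1, 0.5, b=2.0, seed=0)
        assert energy(net, np.zeros(40), condition(1, "x_only")) == pytest.approx(1.0)

    def test_matches_summation_oracle(self, rng):
        net = make_network(15, 2, 0.4, b=3.0, seed=6, theta=0.2)
        r = rng.uniform(0, 2, 15)
        stim = StimulusEnsemble(rng.uniform(0, 1, 2), rng.uniform(0, 1, 2))
        assert energy(net, r, stim) == pytest.approx(loop_energy(net, r, stim))

    def test_negative_rates_rejected(self):
        net = make_network(10, 1, 0.5, b=2.0, seed=0)
        r = np.zeros(10)
        r[3] = -0.1
        with pytest.raises(ParameterError):
            energy(net, r, condition(1, "match"))


class TestPrune:
    def test_keep_all_is_identity(self, small_trained_net):
        pruned = prune(small_trained_net, 1.0, seed=0)
        assert np.allclose(pruned.J, small_trained_net.J)
        assert not pruned.pruned

    def test_half_pruning_zero_fraction(self):
        net = make_network(200, 1, 0.5, b=2.0, seed=0)
        pruned = prune(net, 0.5, seed=1)
        off = ~np.eye(200, dtype=bool)
        zero_frac = np.mean(pruned.J[off] == 0.0)
        # binomial CI around 0.5 for 200*199 entries
        assert abs(zero_frac - 0.5) < 0.01
        assert pruned.pruned
        assert not np.allclose(pruned.J, pruned.J.T)

    def test_keep_prob_domain(self, small_trained_net):
        for bad in (0.0, -0.2, 1.5):
            with pytest.raises(ParameterError):
                prune(small_trained_net, bad, seed=0)

    def test_internal_prediction_stable_under_pruning(self):
        """The stimulus-specific readout survives random synapse removal."""
        net = make_network(800, 2, 0.9, b=5.0, seed=3)
        pruned = prune(net, 0.5, seed=4)
        stim = condition(2, "x_only", pair=0)
        xh = {}
        for tag, n in (("full", net), ("pruned", pruned)):
            traj = simulate(n, stim, T=12.0, record_dt=0.5)
            late = traj.rates()[-8:]  # average over the late window
            xh[tag] = np.mean([n.readouts(r)[0][0] for r in late])
        assert xh["pruned"] == pytest.approx(xh["full"], abs=0.15)
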