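import numpy as np
import pytest

from predinet import (
    balance_levels,
    calibrate_gain_to_balance,
    condition,
    invert_variance_ratio,
    make_network,
    optimal_gain,
    pair_geometry,
    steady_state,
    variance_ratio,
)
from predinet.network import RecurrentNetwork
from predinet.errors import ConvergenceError, NonIdentifiableError, ParameterError, RangeError
from predinet.observables import time_dependent_balance, variance_ratio_range


def _no_recurrence_net(N=100, b=3.0, seed=0):
    """Network with the recurrent matrix zeroed out (I^R = 0)."""
    net = make_network(N, 1, 0.5, b=b, seed=seed)
    return RecurrentNetwork(
        params=net.params, weights=net.weights, pruned=True, _J_dense=np.zeros((N, N))
    )


class TestBalance:
    def test_unity_without_recurrence(self):
        net = _no_recurrence_net()
        prof = balance_levels(net, condition(1, "x_only"))
        assert np.allclose(prof.B[~prof.flagged], 1.0)

    def test_match_balance_tightens_and_mismatch_loosens_with_learning(self):
        med = {"match": [], "x_only": []}
        for mu in (0.0, 0.5, 0.97):
            net = make_network(2000, 1, mu, b=20.0, seed=1)
            for lab in med:
                med[lab].append(balance_levels(net, condition(1, lab)).median)
        assert med["match"][0] < med["match"][1] < med["match"][2]
        assert med["x_only"][0] > med["x_only"][2]

    def test_mismatch_distribution_develops_mass_at_zero(self):
        """Learning moves mismatch balance mass toward B ~ 0.

        Before learning every neuron sits at the same mismatch balance
        (1 + b/2); afterwards the distribution spreads with a heavy
        concentration of loosely balanced (B < 1) neurons.
        """
        frac_low = {}
        for mu in (0.0, 0.97):
            net = make_network(4000, 1, mu, b=170.0, seed=2)
            prof = balance_levels(net, condition(1, "x_only"))
            B = prof.B[~prof.flagged]
            frac_low[mu] = np.mean(B < 1.0)
        assert frac_low[0.0] < 0.005
        assert frac_low[0.97] > 0.01
        assert frac_low[0.97] > 10 * frac_low[0.0]

    def test_refuses_unconverged_state(self, small_trained_net):
        ss = steady_state(small_trained_net, condition(2, "match"))
        ss.residual = 1.0
        with pytest.raises(ConvergenceError):
            balance_levels(small_trained_net, condition(2, "match"), ss=ss)

    def test_time_dependent_form_masks_small_voltages(self):
        B, valid = time_dependent_balance(
            h=np.array([1.0, 1e-12]), IF=np.array([0.5, 0.5]), b=2.0
        )
        assert valid[0] and not valid[1]
        assert B[0] == pytest.approx(1.0)
        assert np.isnan(B[1])


class TestVarianceRatio:
    @pytest.mark.parametrize("b", [0.5, 1.0, 10.0, 200.0])
    def test_untrained_limit_is_half(self, b):
        assert variance_ratio(b, 0.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("b", [0.5, 1.0, 10.0, 200.0])
    def test_fully_trained_limit_is_quarter(self, b):
        assert variance_ratio(b, 1.0) == pytest.approx(0.25)

    def test_round_trip_inversion(self):
        assert invert_variance_ratio(variance_ratio(5.0, 0.97), 0.97) == pytest.approx(5.0)

    def test_untrained_is_nonidentifiable(self):
        with pytest.raises(NonIdentifiableError):
            invert_variance_ratio(0.5, 0.0)

    def test_out_of_range_ratio_rejected(self):
        lo, hi = variance_ratio_range(0.9)
        with pytest.raises(RangeError):
            invert_variance_ratio(hi * 2, 0.9)

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            variance_ratio(-1.0, 0.5)
        with pytest.raises(ParameterError):
            variance_ratio(1.0, 1.5)


class TestGainCalibration:
    def test_calibration_hits_target_balance(self):
        b = calibrate_gain_to_balance(target=162.0, N=1500, seed=0)
        net = make_network(1500, 1, 0.97, b=b, seed=0)
        med = balance_levels(net, condition(1, "match")).median
        assert med == pytest.approx(162.0, abs=1.0)

    def test_optimal_gain_is_smallest_feasible(self):
        floor = 1.2
        fac = lambda b: make_network(800, 1, 0.9, b=b, seed=3)
        res = optimal_gain(fac, mismatch_rate_floor=floor, b_grid=np.logspace(-1, 2, 10))
        ss_at = steady_state(fac(res.b_star), condition(1, "x_only")).r.mean()
        ss_below = steady_state(fac(res.b_star * 0.9), condition(1, "x_only")).r.mean()
        assert ss_at >= floor
        assert ss_below < floor
        # mismatch response grows with gain on the scanned grid
        assert np.all(np.diff(res.scanned_mismatch_rate) >= -1e-9)

    def test_infeasible_floor_reports_grid(self):
        fac = lambda b: make_network(300, 1, 0.9, b=b, seed=3)
        with pytest.raises(ParameterError, match="grid"):
            optimal_gain(fac, mismatch_rate_floor=1e6, b_grid=np.logspace(-1, 1, 4))


class TestGeometry:
    def test_untrained_responses_uncorrelated(self):
        net = make_network(3000, 1, 0.0, b=5.0, seed=4)
        geo = pair_geometry(net)
        assert abs(geo.cos_xy) < 0.1

    def test_learning_anti_aligns_mismatch_responses(self):
        net = make_network(3000, 1, 0.9, b=20.0, seed=4)
        geo = pair_geometry(net)
        assert geo.cos_xy < -0.2

    def test_mismatch_match_ratio_grows_with_learning(self):
        ratios = []
        for mu in (0.0, 0.9):
            net = make_network(3000, 1, mu, b=5.0, seed=4)
            ratios.append(pair_geometry(net).rate_ratio)
        assert ratios[1] > ratios[0]

    def test_cosines_monotone_in_mu_and_cross_pair_null(self):
        """cos(r_x, r_y) decreases through learning; cross-pair stays near 0."""
        cos_within, cos_cross = [], []
        for mu in (0.0, 0.3, 0.6, 0.9):
            net = make_network(3000, 2, mu, b=20.0, seed=6)
            cos_within.append(pair_geometry(net, pair=0).cos_xy)
            r_x1 = steady_state(net, condition(2, "x_only", pair=0)).r
            r_y2 = steady_state(net, condition(2, "y_only", pair=1)).r
            a, c = r_x1 - r_x1.mean(), r_y2 - r_y2.mean()
            cos_cross.append(float(a @ c / (np.linalg.norm(a) * np.linalg.norm(c))))
        assert np.all(np.diff(cos_within) < 0)
        assert np.all(np.abs(cos_cross) < 0.1)
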