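import numpy as np
import pytest

from predinet import (
    condition,
    decompose,
    fit_gain_am,
    fit_gain_vm,
    generate_am_recording,
    generate_probe_ensemble,
    generate_rsfs_recording,
    generate_vm_recording,
    make_network,
    make_segregated_recording,
    segregation_index,
    steady_state,
    variance_ratio,
)
from predinet.ei import rsfs_correlations
from predinet.errors import ParameterError
from predinet.recordings import SyntheticRecording


@pytest.fixture(scope="module")
def trained_p1_net():
    return make_network(N=4000, P=1, mu=0.97, b=20.0, seed=7)


class TestGenerators:
    def test_vm_recording_deterministic(self, trained_p1_net):
        a = generate_vm_recording(trained_p1_net, seed=3)
        c = generate_vm_recording(trained_p1_net, seed=3)
        assert np.array_equal(a.values, c.values)
        assert a.ground_truth == c.ground_truth

    def test_vm_noiseless_std_ratio_matches_closed_form(self, trained_p1_net):
        """Window variance ratio equals the closed-form expression up to
        finite-N sampling error (all neurons included, no trial noise)."""
        rec = generate_vm_recording(trained_p1_net, n_neurons=4000, n_trials=1,
                                    noise_sd=0.0, seed=1)
        s_match = rec.window_values("match").std()
        s_mism = rec.window_values("mismatch").std()
        expected = variance_ratio(20.0, 0.97)
        assert (s_mism / s_match) ** 2 == pytest.approx(expected, rel=0.1)

    def test_am_mean_change_ratio_matches_model(self, trained_p1_net):
        rec = generate_am_recording(trained_p1_net, n_neurons=815, noise_sd=0.0, seed=2)
        r_pas = rec.response_change("expected", "passive").mean()
        r_act = rec.response_change("expected", "active").mean()
        r_m = steady_state(trained_p1_net, condition(1, "x_only")).r.mean()
        r_xy = steady_state(trained_p1_net, condition(1, "match")).r.mean()
        assert r_pas / r_act == pytest.approx(r_m / r_xy, rel=0.05)

    def test_ground_truth_always_serialized(self, trained_p1_net):
        for rec in (
            generate_vm_recording(trained_p1_net, seed=0),
            generate_am_recording(trained_p1_net, n_neurons=100, seed=0),
        ):
            assert {"b", "mu", "noise_sd", "seed"} <= set(rec.ground_truth)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ParameterError):
            SyntheticRecording(
                kind="rate",
                values=np.zeros((1, 2, 10)),
                neuron_class=np.array(["RS", "RS"]),
                trial_condition=np.array(["passive"]),
                trial_stimulus=np.array(["expected"]),
                windows={"baseline": (0, 6), "evoked": (4, 10)},
            )


class TestGainRecovery:
    def test_vm_fit_recovers_ground_truth(self, trained_p1_net):
        rec = generate_vm_recording(trained_p1_net, seed=5)
        fit = fit_gain_vm(rec, seed=5)
        lo, hi = fit.ci
        assert lo <= 20.0 <= hi
        assert 5.0 < fit.b_hat < 80.0

    def test_am_fit_recovers_ground_truth(self, trained_p1_net):
        rec = generate_am_recording(trained_p1_net, seed=6)
        fit = fit_gain_am(rec, seed=6)
        lo, hi = fit.ci
        assert lo <= 20.0 <= hi

    def test_am_bootstrap_spread_shrinks_with_draws(self, trained_p1_net):
        """CLT scaling: quadrupling the resample size roughly halves the
        spread of the bootstrap fits."""
        rec = generate_am_recording(trained_p1_net, seed=6)
        sd_small = np.std(fit_gain_am(rec, n_draws=100, n_repeats=150, seed=1).fits)
        sd_large = np.std(fit_gain_am(rec, n_draws=400, n_repeats=150, seed=2).fits)
        assert sd_large < sd_small
        assert sd_small / sd_large == pytest.approx(2.0, abs=0.9)


class TestProbeEnsemble:
    def test_overlap_domain(self):
        with pytest.raises(ParameterError):
            generate_probe_ensemble([1.5], N=200, b=5.0, seed=0)

    def test_sparsity_target_sets_threshold(self):
        rec = generate_probe_ensemble([0.5], N=1000, b=20.0, sparsity_f=0.25,
                                      noise_sd=0.0, seed=1)
        assert rec.ground_truth["theta"] > 0
        active = (rec.response_change("expected", "passive") > 1e-9).mean()
        assert active == pytest.approx(0.25, abs=0.08)


class TestSegregatedNull:
    def test_constructed_null_is_fully_segregated(self):
        rec = make_segregated_recording(seed=4)
        res = segregation_index(rec, "expected", "probe")
        assert res.segregation_index == pytest.approx(1.0, abs=1e-9)

    def test_model_is_less_segregated_than_null(self):
        null = segregation_index(make_segregated_recording(seed=4), "expected", "probe")
        model = segregation_index(
            generate_probe_ensemble([0.3], N=1500, b=20.0, seed=4), "expected", "probe_0"
        )
        assert model.segregation_index < null.segregation_index - 0.02


class TestRsFsRecordings:
    def test_private_inhibition_fs_mirrors_rs(self):
        """At lambda = 0 every FS unit copies an RS parent, so the class-level
        correlations coincide (up to trial noise and sampling)."""
        net = make_network(N=400, P=2, mu=[0.97, 0.0], b=20.0, seed=1)
        ei = decompose(net, 0.0, seed=1)
        rec = generate_rsfs_recording(ei, noise_sd=0.05, seed=2)
        cors = rsfs_correlations(rec)
        for stim in ("expected", "probe"):
            assert cors[("FS", stim)] == pytest.approx(cors[("RS", stim)], abs=0.1)

    def test_mixed_inhibition_decouples_fs_from_learning(self):
        """At lambda = 0.6 the FS movement/passive correlation changes less
        between probe (before) and expected (after learning) than RS."""
        net = make_network(N=400, P=2, mu=[0.97, 0.0], b=20.0, seed=1)
        ei = decompose(net, 0.6, seed=1)
        rec = generate_rsfs_recording(ei, noise_sd=0.05, seed=2)
        cors = rsfs_correlations(rec)
        drop_rs = cors[("RS", "probe")] - cors[("RS", "expected")]
        drop_fs = cors[("FS", "probe")] - cors[("FS", "expected")]
        assert drop_fs < drop_rs
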