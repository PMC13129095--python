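import numpy as np
import pytest

from predinet import (
    PulseProtocol,
    StepProtocol,
    classification_sigma,
    classify_pair,
    condition,
    make_network,
    run_pulse_protocol,
    run_step_protocol,
    simulate,
    steady_state,
    time_resolved_celltypes,
)
from predinet import balance_levels
from predinet.errors import DimensionError, ParameterError


class TestPulseProtocols:
    def test_leak_dominated_decay_timescale(self):
        """With negligible recurrence the post-pulse decay is the membrane
        constant (tau = 1)."""
        net = make_network(300, 2, 0.0, b=0.05, seed=0)
        _, m = run_pulse_protocol(net, PulseProtocol(condition="x_only", amplitude=50.0))
        assert m.tau_decay == pytest.approx(1.0, abs=0.15)

    def test_learning_slows_response_decay(self):
        taus = {}
        for mu in (0.0, 0.9):
            net = make_network(600, 2, mu, b=5.0, seed=0)
            _, m = run_pulse_protocol(net, PulseProtocol(delta_t=0.01, condition="match"))
            taus[mu] = m.tau_decay
        assert taus[0.9] > taus[0.0]

    def test_match_suppression_specific_to_associated_pairs(self):
        """Cross-pair 'matches' behave like untrained stimuli: no suppression."""
        net = make_network(600, 2, 0.9, b=5.0, seed=0)
        _, same = run_pulse_protocol(net, PulseProtocol(delta_t=0.01, condition="match"))
        _, cross = run_pulse_protocol(
            net, PulseProtocol(delta_t=0.01, condition="cross_pair", cross_partner=1)
        )
        net0 = make_network(600, 2, 0.0, b=5.0, seed=0)
        _, untrained = run_pulse_protocol(net0, PulseProtocol(delta_t=0.01, condition="match"))
        assert same.ratio_post > 2.0
        assert cross.ratio_post < 1.5
        assert abs(cross.ratio_post - untrained.ratio_post) < 0.5

    def test_suppression_grows_as_interval_shrinks(self):
        net = make_network(600, 2, 0.9, b=5.0, seed=0)
        _, short = run_pulse_protocol(net, PulseProtocol(delta_t=0.01, condition="match"))
        _, long = run_pulse_protocol(net, PulseProtocol(delta_t=1.0, condition="match"))
        assert short.ratio_post > long.ratio_post

    def test_readout_norm_decays_slower_after_learning(self):
        norms = {}
        for mu in (0.0, 0.9):
            net = make_network(600, 2, mu, b=5.0, seed=0)
            _, m = run_pulse_protocol(net, PulseProtocol(delta_t=0.01, condition="match"))
            post = (m.times >= m.window[0]) & (m.times <= m.window[1])
            norms[mu] = m.readout_norm[post].mean() / (m.readout_norm.max() + 1e-12)
        assert norms[0.9] > norms[0.0]

    def test_window_validation(self):
        net = make_network(100, 2, 0.5, b=2.0, seed=1)
        with pytest.raises(ParameterError):
            run_pulse_protocol(net, PulseProtocol(condition="match"), T=0.4)
        with pytest.raises(ParameterError):
            PulseProtocol(delta_t=-1.0)
        with pytest.raises(ParameterError):
            PulseProtocol(condition="cross_pair")


class TestStepProtocols:
    def test_long_step_balance_converges_to_static_definition(self):
        net = make_network(400, 2, 0.9, b=5.0, seed=2)
        proto = StepProtocol(pair=0, delta_t=0.0, step_width=12.0, condition="x_only")
        _, times, med = run_step_protocol(net, proto, T=12.0)
        static_med = balance_levels(net, condition(2, "x_only", pair=0)).median
        late = np.nanmedian(med[times > 10.0])
        assert late == pytest.approx(static_med, rel=0.05)

    def test_transient_tight_balance_at_predicted_onset(self):
        net = make_network(600, 2, 0.9, b=5.0, seed=2)
        proto = StepProtocol(pair=0, delta_t=1.0, step_width=4.0, condition="match")
        _, times, med = run_step_protocol(net, proto, T=6.0)
        pre = np.nanmedian(med[(times > 1.0) & (times < 1.5)])
        peak = np.nanmax(med[(times >= 1.5) & (times <= 2.5)])
        assert peak > 1.3 * pre

    def test_zero_drive_protocol_rejected(self):
        net = make_network(100, 2, 0.5, b=2.0, seed=1)
        proto = StepProtocol(pair=0, delta_t=0.0, step_width=0.0, amplitude=0.0)
        with pytest.raises(ParameterError, match="balance"):
            run_step_protocol(net, proto, T=2.0)


class TestTimeResolvedCellTypes:
    def test_prestimulus_counts_are_zero(self):
        net = make_network(400, 2, 0.9, b=5.0, seed=3)
        stim_m = PulseProtocol(condition="x_only", t_on=0.5).stim_fn(2)
        stim_xy = PulseProtocol(condition="match", delta_t=0.0, t_on=0.5).stim_fn(2)
        tm = simulate(net, stim_m, T=2.0, record_dt=0.25)
        txy = simulate(net, stim_xy, T=2.0, record_dt=0.25)
        sigma = classification_sigma(400, 2, 5.0, 3)
        counts = time_resolved_celltypes(tm, txy, sigma)
        assert counts["R"][0] == 0 and counts["PE"][0] == 0

    def test_long_step_labels_match_static_classifier(self):
        net = make_network(400, 2, 0.9, b=5.0, seed=3)
        sx = StepProtocol(pair=0, delta_t=0.0, step_width=20.0, condition="x_only").stim_fn(2)
        sxy = StepProtocol(pair=0, delta_t=0.0, step_width=20.0, condition="match").stim_fn(2)
        tm = simulate(net, sx, T=15.0, record_dt=5.0)
        txy = simulate(net, sxy, T=15.0, record_dt=5.0)
        sigma = classification_sigma(400, 2, 5.0, 3)
        counts = time_resolved_celltypes(tm, txy, sigma)
        h_x = steady_state(net, condition(2, "x_only", pair=0)).h
        h_xy = steady_state(net, condition(2, "match", pair=0)).h
        static = classify_pair(h_x, h_xy, sigma)
        assert counts["R"][-1] == (static["label"] == "R").sum()
        assert counts["PE"][-1] == (static["label"] == "PE").sum()

    def test_mismatched_grids_rejected(self):
        net = make_network(100, 2, 0.5, b=2.0, seed=1)
        s = StepProtocol(pair=0).stim_fn(2)
        a = simulate(net, s, T=1.0, record_dt=0.5)
        c = simulate(net, s, T=1.0, record_dt=0.25)
        with pytest.raises(DimensionError):
            time_resolved_celltypes(a, c, 1.0)


class TestBalancePeakVsDimension:
    def test_transient_balance_peak_decreases_with_stimulus_load(self):
        """The tight-balance episode at the predicted-stimulus onset weakens
        as the number of learned pairs grows (interference loosens balance)."""
        N = 600
        peaks = []
        for alpha in (2 / N, 0.2, 0.5):
            P = max(2, int(round(alpha * N)))
            net = make_network(N, P, 0.9, b=5.0, seed=2)
            proto = StepProtocol(pair=0, delta_t=1.0, step_width=4.0)
            _, times, med = run_step_protocol(net, proto, T=6.0)
            peaks.append(np.nanmax(med[(times >= 1.5) & (times <= 2.5)]))
        assert peaks[0] > peaks[1] > peaks[2]
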