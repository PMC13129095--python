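"""Transient stimulation protocols: pulses, steps, and time-resolved analyses.

Pulse protocols probe the network's ability to generate and briefly maintain
a prediction: in the match condition the y pulse lags the x pulse by an
interval delta_t, so the association must bridge the gap.  After learning the
post-removal response decays more slowly than before learning, and the match
response (relative to the mismatches) is suppressed, specifically for pulses
of associated stimuli.

Step protocols keep the feedforward drive on, so the time-resolved balance

    B_i(t) = | b I^F_i(t) / h_i(t) |

is defined throughout (it reduces to the static definition at steady state);
after learning the onset of the second, predicted stimulus produces a
transient episode of tight balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .celltypes import classify_pair
from .dynamics import Trajectory, simulate
from .errors import DimensionError, ParameterError
from .network import RecurrentNetwork
from .observables import time_dependent_balance
from .stimuli import StimulusEnsemble

PULSE_CONDITIONS = ("x_only", "y_only", "match", "cross_pair")


@dataclass(frozen=True)
class PulseProtocol:
    """Timed pulses of one stimulus-pair (or a cross-pair control)."""

    pair: int = 0
    delta_t: float = 0.1         # y-onset lag after x-onset (membrane units)
    pulse_width: float = 0.1
    amplitude: float = 1.0
    condition: str = "match"
    cross_partner: int | None = None
    t_on: float = 0.5            # onset of the (first) pulse

    def __post_init__(self):
        if self.condition not in PULSE_CONDITIONS:
            raise ParameterError(f"condition must be one of {PULSE_CONDITIONS}")
        if self.delta_t < 0:
            raise ParameterError("delta_t must be >= 0")
        if self.condition == "cross_pair" and self.cross_partner is None:
            raise ParameterError("cross_pair protocol needs a cross_partner")

    @property
    def offset(self) -> float:
        """Time at which the last pulse ends."""
        t = self.t_on + self.pulse_width
        if self.condition in ("match", "cross_pair"):
            t = max(t, self.t_on + self.delta_t + self.pulse_width)
        return t

    def stim_fn(self, P: int):
        def fn(t: float) -> StimulusEnsemble:
            x = np.zeros(P)
            y = np.zeros(P)
            if self.condition in ("x_only", "match", "cross_pair"):
                if self.t_on <= t < self.t_on + self.pulse_width:
                    x[self.pair] = self.amplitude
            y_pair = self.pair if self.condition != "cross_pair" else self.cross_partner
            if self.condition in ("y_only", "match", "cross_pair"):
                t_y = self.t_on + (self.delta_t if self.condition != "y_only" else 0.0)
                if t_y <= t < t_y + self.pulse_width:
                    y[y_pair] = self.amplitude
            return StimulusEnsemble(x, y, label=self.condition)

        return fn


@dataclass
class TransientMetrics:
    ratio_post: float            # mean mismatch rate / mean paired rate, post-removal
    tau_decay: float             # fitted exponential decay timescale of the mismatch
    readout_norm: np.ndarray     # ||r_paired(t) - r_x_only(t)||
    times: np.ndarray
    window: tuple[float, float]


def _fit_tau(times: np.ndarray, mean_rate: np.ndarray, floor: float = 1e-6) -> float:
    keep = mean_rate >= floor
    if keep.sum() < 3:
        raise ParameterError("too few above-floor samples to fit a decay timescale")
    t, y = times[keep], np.log(mean_rate[keep])
    slope = np.polyfit(t, y, 1)[0]
    if slope >= 0:
        return np.inf
    return float(-1.0 / slope)


def run_pulse_protocol(
    net: RecurrentNetwork,
    protocol: PulseProtocol,
    T: float | None = None,
    dt: float | None = None,
    record_dt: float = 0.02,
    post_window: tuple[float, float] = (0.5, 3.0),
) -> tuple[dict[str, Trajectory], TransientMetrics]:
    """Simulate the paired protocol plus its two mismatch references.

    The suppression ratio and the decay timescale are measured in the
    declared post-removal window ``[offset + post_window[0],
    offset + post_window[1]]``.
    """
    offset = protocol.offset
    if T is None:
        T = offset + post_window[1] + 1.0
    if offset >= T:
        raise ParameterError("pulses do not fit within the simulation horizon")
    theta = net.params.theta
    trajs: dict[str, Trajectory] = {}
    for cond in ("x_only", "y_only", protocol.condition):
        if cond in trajs:
            continue
        proto_c = PulseProtocol(
            pair=protocol.pair,
            delta_t=protocol.delta_t,
            pulse_width=protocol.pulse_width,
            amplitude=protocol.amplitude,
            condition=cond,
            cross_partner=protocol.cross_partner,
            t_on=protocol.t_on,
        )
        trajs[cond] = simulate(net, proto_c.stim_fn(net.P), T=T, dt=dt, record_dt=record_dt)
    times = trajs["x_only"].times
    w0, w1 = offset + post_window[0], offset + post_window[1]
    in_win = (times >= w0) & (times <= w1)
    if not np.any(in_win):
        raise ParameterError("post-removal measurement window is empty")
    mism = 0.5 * (
        trajs["x_only"].rates(theta).mean(axis=1) + trajs["y_only"].rates(theta).mean(axis=1)
    )
    paired = trajs[protocol.condition].rates(theta).mean(axis=1)
    denom = paired[in_win].mean()
    ratio = float(mism[in_win].mean() / denom) if denom > 0 else np.inf
    tau = _fit_tau(times[in_win], mism[in_win])
    dr = np.linalg.norm(
        trajs[protocol.condition].rates(theta) - trajs["x_only"].rates(theta), axis=1
    )
    return trajs, TransientMetrics(
        ratio_post=ratio, tau_decay=tau, readout_norm=dr, times=times, window=(w0, w1)
    )


@dataclass(frozen=True)
class StepProtocol:
    """Sustained steps: x on at t_on, y joining after delta_t."""

    pair: int = 0
    delta_t: float = 1.0
    step_width: float = 4.0
    amplitude: float = 1.0
    condition: str = "match"
    t_on: float = 0.5

    def stim_fn(self, P: int):
        def fn(t: float) -> StimulusEnsemble:
            x = np.zeros(P)
            y = np.zeros(P)
            if self.condition in ("x_only", "match"):
                if self.t_on <= t < self.t_on + self.step_width:
                    x[self.pair] = self.amplitude
            if self.condition in ("y_only", "match"):
                t_y = self.t_on + self.delta_t
                if t_y <= t < t_y + self.step_width:
                    y[self.pair] = self.amplitude
            return StimulusEnsemble(x, y, label=self.condition)

        return fn


def run_step_protocol(
    net: RecurrentNetwork,
    protocol: StepProtocol,
    T: float | None = None,
    dt: float | None = None,
    record_dt: float = 0.02,
    h_floor: float = 1e-8,
):
    """Simulate a step protocol and the time-resolved balance level.

    Returns (trajectory, times, median_B) with the median taken over neurons
    with nonzero feedforward drive and |h| above the floor.  Raises if the
    feedforward input is zero throughout the evaluation window.
    """
    if T is None:
        T = protocol.t_on + protocol.delta_t + protocol.step_width + 1.0
    stim_fn = protocol.stim_fn(net.P)
    traj = simulate(net, stim_fn, T=T, dt=dt, record_dt=record_dt)
    med = np.full(traj.n_times, np.nan)
    any_drive = False
    for i, t in enumerate(traj.times):
        IF = net.feedforward(stim_fn(t))
        if not np.any(IF):
            continue
        any_drive = True
        B, valid = time_dependent_balance(traj.H[i], IF, net.params.b, floor=h_floor)
        if np.any(valid):
            med[i] = np.nanmedian(B[valid])
    if not any_drive:
        raise ParameterError("feedforward input is zero everywhere; balance undefined")
    return traj, traj.times, med


def time_resolved_celltypes(
    traj_mismatch: Trajectory,
    traj_match: Trajectory,
    sigma: float,
    theta: float = 0.0,
    center: bool = False,
    second_pair: tuple[Trajectory, Trajectory] | None = None,
):
    """Classify every neuron at every recorded time with a fixed sigma.

    Returns a dict of per-time counts (R, PE); when a second pair's
    trajectories are supplied, also the per-time count of mixed neurons
    (R for one pair, PE for the other, among dually-responsive neurons).
    """
    if traj_mismatch.H.shape != traj_match.H.shape or not np.allclose(
        traj_mismatch.times, traj_match.times
    ):
        raise DimensionError("trajectories must share the time grid")
    n_t = traj_mismatch.n_times
    counts = {"times": traj_mismatch.times, "R": np.zeros(n_t, dtype=int),
              "PE": np.zeros(n_t, dtype=int)}
    if second_pair is not None:
        counts["mixed"] = np.zeros(n_t, dtype=int)
    for i in range(n_t):
        tab = classify_pair(traj_mismatch.H[i], traj_match.H[i], sigma, center=center)
        counts["R"][i] = int((tab["label"] == "R").sum())
        counts["PE"][i] = int((tab["label"] == "PE").sum())
        if second_pair is not None:
            t2 = classify_pair(second_pair[0].H[i], second_pair[1].H[i], sigma, center=center)
            dually = (tab["responsive"] & t2["responsive"]).to_numpy()
            l1 = tab["label"].to_numpy()
            l2 = t2["label"].to_numpy()
            mixed = dually & (((l1 == "R") & (l2 == "PE")) | ((l1 == "PE") & (l2 == "R")))
            counts["mixed"][i] = int(mixed.sum())
    return counts
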