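"""Synthetic trial-based "experimental" recordings with known ground truth.

Every generator emulates the layout of one of the predictive-coding
experiments the model is compared against, from a ground-truth model network
whose parameters are serialized alongside the data:

* intracellular voltage traces around a visuomotor decoupling event
  (32 neurons; match window -0.1..0 s, mismatch window 0..0.1 s),
* extracellular firing-rate changes in an audiomotor task (regular-spiking
  neurons; baseline -0.1..0 s, evoked 0..0.06 s; passive = mismatch,
  movement = match),
* a probe-stimulus ensemble: untrained sounds with controlled weight overlap
  to the trained (expected) sound, in active and passive conditions,
* RS/FS-labelled recordings from an excitatory/inhibitory decomposition.

Downstream fits (gain b from variance or mean-rate ratios, lambda_EI from
FS-population correlations) are validated by parameter recovery against the
serialized ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import steady_state
from .errors import ParameterError, RangeError
from .network import RecurrentNetwork, make_network
from .observables import invert_variance_ratio, variance_ratio_range
from .stimuli import StimulusEnsemble, condition
from .weights import MU_TRAINED

BIN_WIDTH = 0.01  # seconds


@dataclass
class SyntheticRecording:
    """Trials x neurons x time-bins array with experiment-style metadata."""

    kind: str                       # 'voltage' or 'rate'
    values: np.ndarray              # (n_trials, n_neurons, n_bins)
    neuron_class: np.ndarray        # 'RS' / 'FS' per neuron
    trial_condition: np.ndarray     # 'active' (movement/match) or 'passive' (mismatch)
    trial_stimulus: np.ndarray      # 'expected', 'probe', 'probe_1', ...
    windows: dict                   # name -> (first_bin, last_bin_exclusive)
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        spans = sorted(self.windows.values())
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if a1 > b0:
                raise ParameterError("recording windows must be ordered and non-overlapping")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[1]

    def window_values(self, window: str, stimulus=None, cond=None) -> np.ndarray:
        """All (trial, neuron, bin) samples of one window, optionally filtered."""
        i0, i1 = self.windows[window]
        sel = np.ones(self.values.shape[0], dtype=bool)
        if stimulus is not None:
            sel &= self.trial_stimulus == stimulus
        if cond is not None:
            sel &= self.trial_condition == cond
        return self.values[sel][:, :, i0:i1]

    def response_change(self, stimulus: str, cond: str) -> np.ndarray:
        """Per-neuron trial-averaged evoked-minus-baseline response."""
        evoked = self.window_values("evoked", stimulus, cond).mean(axis=(0, 2))
        base = self.window_values("baseline", stimulus, cond).mean(axis=(0, 2))
        return evoked - base

    def to_frame(self) -> pd.DataFrame:
        n_tr, n_nr, n_b = self.values.shape
        tr, nr, bi = np.meshgrid(
            np.arange(n_tr), np.arange(n_nr), np.arange(n_b), indexing="ij"
        )
        return pd.DataFrame(
            {
                "trial": tr.ravel(),
                "neuron_id": nr.ravel(),
                "class": self.neuron_class[nr.ravel()],
                "condition": self.trial_condition[tr.ravel()],
                "stimulus": self.trial_stimulus[tr.ravel()],
                "time_bin": bi.ravel(),
                "value": self.values.ravel(),
            }
        )


def _default_noise(signal: np.ndarray) -> float:
    return 0.2 * float(np.std(signal))


def generate_vm_recording(
    net: RecurrentNetwork,
    n_neurons: int = 32,
    n_trials: int = 20,
    noise_sd: float | None = None,
    seed: int = 0,
    pair: int = 0,
) -> SyntheticRecording:
    """Intracellular-style voltage traces around a decoupling event.

    Bins 0..9 (match window, -0.1..0 s): the model's match-condition voltage;
    bins 10..19 (mismatch window): the x-only mismatch voltage; i.i.d.
    Gaussian trial noise on every sample.
    """
    rng = np.random.default_rng(seed)
    h_match = steady_state(net, condition(net.P, "match", pair=pair)).h
    h_mism = steady_state(net, condition(net.P, "x_only", pair=pair)).h
    if noise_sd is None:
        noise_sd = _default_noise(h_mism)
    idx = rng.choice(net.N, size=n_neurons, replace=False)
    traces = np.concatenate(
        [np.tile(h_match[idx], (10, 1)).T, np.tile(h_mism[idx], (10, 1)).T], axis=1
    )
    values = traces[None, :, :] + noise_sd * rng.standard_normal((n_trials, n_neurons, 20))
    return SyntheticRecording(
        kind="voltage",
        values=values,
        neuron_class=np.array(["RS"] * n_neurons),
        trial_condition=np.array(["passive"] * n_trials),
        trial_stimulus=np.array(["expected"] * n_trials),
        windows={"match": (0, 10), "mismatch": (10, 20)},
        ground_truth={
            "b": net.params.b,
            "mu": float(net.weights.mu[pair]),
            "noise_sd": float(noise_sd),
            "seed": seed,
            "N_model": net.N,
        },
    )


@dataclass
class GainFit:
    b_hat: float
    ci: tuple[float, float]
    fits: np.ndarray
    ratio: float  # point-estimate of the fitted ratio (variance or mean-rate)


def _safe_invert(ratio_sq: float, mu: float, b_cap: float = 1e6) -> float:
    lo, hi = variance_ratio_range(mu)
    if ratio_sq >= hi:
        return b_cap
    if ratio_sq <= lo:
        return 0.0
    try:
        return invert_variance_ratio(ratio_sq, mu, b_max=b_cap)
    except RangeError:
        return b_cap if ratio_sq > hi else 0.0


def fit_gain_vm(
    recording: SyntheticRecording,
    mu: float = MU_TRAINED,
    n_samples: int = 50,
    n_repeats: int = 100,
    seed: int = 0,
) -> GainFit:
    """Recover the gain from the voltage std ratio of the two windows.

    Each repeat resamples neurons with replacement (cluster bootstrap) and
    draws ``n_samples`` voltage values from each window; the squared std
    ratio (mismatch/match) is inverted through the closed-form variance
    ratio.  The 2.5-97.5 percentile band of the repeats is the CI.
    """
    rng = np.random.default_rng(seed)
    vm = recording.window_values("match")    # (trials, neurons, bins)
    vx = recording.window_values("mismatch")
    n_nr = vm.shape[1]

    def one_fit(neuron_idx):
        pool_m = vm[:, neuron_idx, :].reshape(vm.shape[0], len(neuron_idx), -1)
        pool_x = vx[:, neuron_idx, :].reshape(vx.shape[0], len(neuron_idx), -1)
        flat_m, flat_x = pool_m.ravel(), pool_x.ravel()
        sm = rng.choice(flat_m, size=n_samples, replace=True)
        sx = rng.choice(flat_x, size=n_samples, replace=True)
        ratio = np.std(sx) / np.std(sm)
        return _safe_invert(ratio**2, mu), ratio**2

    b_point, ratio_point = one_fit(np.arange(n_nr))
    fits = np.array(
        [one_fit(rng.integers(0, n_nr, size=n_nr))[0] for _ in range(n_repeats)]
    )
    lo, hi = np.percentile(fits, [2.5, 97.5])
    return GainFit(b_hat=float(np.median(fits)), ci=(float(lo), float(hi)),
                   fits=fits, ratio=float(ratio_point))


def generate_am_recording(
    net: RecurrentNetwork,
    n_neurons: int = 815,
    n_trials: int = 20,
    noise_sd: float | None = None,
    baseline_rate: float = 2.0,
    seed: int = 0,
    pair: int = 0,
) -> SyntheticRecording:
    """Extracellular-style firing-rate trials in passive and movement conditions.

    Baseline window -0.1..0 s at a constant spontaneous rate; evoked window
    0..0.06 s at spontaneous + model response.  Passive trials carry the
    x-only (mismatch) response, movement trials the match response.
    """
    rng = np.random.default_rng(seed)
    r_mism = steady_state(net, condition(net.P, "x_only", pair=pair)).r
    r_match = steady_state(net, condition(net.P, "match", pair=pair)).r
    if noise_sd is None:
        noise_sd = _default_noise(r_mism)
    replace = n_neurons > net.N
    idx = rng.choice(net.N, size=n_neurons, replace=replace)
    n_bins = 16  # 10 baseline + 6 evoked
    conds, stims, trials = [], [], []
    for cond_name, r in (("passive", r_mism), ("active", r_match)):
        base = np.full((n_trials, n_neurons, n_bins), baseline_rate)
        base[:, :, 10:] += r[idx][None, :, None]
        trials.append(base)
        conds += [cond_name] * n_trials
        stims += ["expected"] * n_trials
    values = np.concatenate(trials, axis=0)
    values = values + noise_sd * rng.standard_normal(values.shape)
    values = np.maximum(values, 0.0)
    return SyntheticRecording(
        kind="rate",
        values=values,
        neuron_class=np.array(["RS"] * n_neurons),
        trial_condition=np.array(conds),
        trial_stimulus=np.array(stims),
        windows={"baseline": (0, 10), "evoked": (10, 16)},
        ground_truth={
            "b": net.params.b,
            "mu": float(net.weights.mu[pair]),
            "noise_sd": float(noise_sd),
            "baseline_rate": baseline_rate,
            "seed": seed,
            "N_model": net.N,
        },
    )


def fit_gain_am(
    recording: SyntheticRecording,
    mu: float = MU_TRAINED,
    n_draws: int = 400,
    n_repeats: int = 100,
    seed: int = 0,
) -> GainFit:
    """Recover the gain from the mean firing-rate-change ratio.

    For ReLU responses with centered Gaussian voltages the mean rate is
    proportional to the voltage std, so the passive/movement mean-change
    ratio squared equals the closed-form variance ratio, which is inverted
    for b.  Repeats resample ``n_draws`` per-neuron change values with
    replacement.
    """
    rng = np.random.default_rng(seed)
    d_pass = recording.response_change("expected", "passive")
    d_act = recording.response_change("expected", "active")
    n_nr = d_pass.shape[0]

    def one_fit(idx):
        m_pass, m_act = d_pass[idx].mean(), d_act[idx].mean()
        if m_act <= 0 or m_pass <= 0:
            return np.nan, np.nan
        ratio = m_pass / m_act
        return _safe_invert(ratio**2, mu), ratio**2

    b_point, ratio_point = one_fit(np.arange(n_nr))
    fits = np.array(
        [one_fit(rng.integers(0, n_nr, size=n_draws))[0] for _ in range(n_repeats)]
    )
    fits = fits[np.isfinite(fits)]
    lo, hi = np.percentile(fits, [2.5, 97.5])
    return GainFit(b_hat=float(np.median(fits)), ci=(float(lo), float(hi)),
                   fits=fits, ratio=float(ratio_point))


def generate_probe_ensemble(
    overlaps,
    N: int = 2000,
    b: float = 20.0,
    mu: float = MU_TRAINED,
    sparsity_f: float | None = None,
    noise_sd: float | None = None,
    n_trials: int = 20,
    n_neurons: int | None = None,
    seed: int = 0,
) -> SyntheticRecording:
    """Expected sound plus untrained probe sounds with controlled similarity.

    The network is trained on a single pair (expected sound w_e, movement
    v_e).  Each probe enters through an untrained weight vector
    w_p = rho * w_e + sqrt(1-rho^2) * xi, so the stimulus overlap rho dials the
    representation similarity.  Active trials pair the sound with the trained
    movement (x_s = 1 with y_e = 1); passive trials present the sound alone.

    ``sparsity_f`` sets the ReLU threshold from the (1-f) quantile of the
    threshold-free passive voltage distribution of the expected sound, an
    operational mapping from a target responsive fraction to theta.
    """
    overlaps = np.atleast_1d(np.asarray(overlaps, dtype=float))
    if np.any(overlaps < 0) or np.any(overlaps > 1):
        raise ParameterError("overlaps must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    net0 = make_network(N=N, P=1, mu=mu, b=b, seed=int(rng.integers(2**31)))
    w_e = net0.weights.W[:, 0]
    v_e = net0.weights.V[:, 0]
    theta = 0.0
    if sparsity_f is not None:
        h_pass = steady_state(net0, IF=w_e).h
        theta = float(np.quantile(h_pass, 1 - sparsity_f))
    from .network import NetworkParams, RecurrentNetwork as _RN

    net = _RN(
        params=NetworkParams(b=b, theta=theta, tol=net0.params.tol),
        weights=net0.weights,
    )
    stim_names = ["expected"] + [f"probe_{j}" for j in range(len(overlaps))]
    inputs = {"expected": w_e}
    for j, rho in enumerate(overlaps):
        xi = rng.standard_normal(N)
        inputs[f"probe_{j}"] = rho * w_e + np.sqrt(1 - rho**2) * xi
    r_move = steady_state(net, IF=v_e).r  # movement alone (lever, no sound)
    rates = {}
    for s, w_s in inputs.items():
        rates[(s, "passive")] = (np.zeros(N), steady_state(net, IF=w_s).r)
        # in active trials the movement signal precedes the sound, so it is
        # present in the baseline window as well; response *changes* thereby
        # cancel the shared movement component, as in the experiment
        rates[(s, "active")] = (r_move, steady_state(net, IF=w_s + v_e).r)
    if noise_sd is None:
        noise_sd = _default_noise(rates[("expected", "passive")][1])
    if n_neurons is None:
        n_neurons = N
    idx = rng.choice(N, size=n_neurons, replace=False)
    n_bins = 16
    blocks, conds, stims = [], [], []
    for s in stim_names:
        for cnd in ("passive", "active"):
            base, evoked = rates[(s, cnd)]
            block = np.zeros((n_trials, n_neurons, n_bins))
            block[:, :, :10] = base[idx][None, :, None]
            block[:, :, 10:] = evoked[idx][None, :, None]
            blocks.append(block)
            conds += [cnd] * n_trials
            stims += [s] * n_trials
    values = np.concatenate(blocks, axis=0)
    values = np.maximum(values + noise_sd * rng.standard_normal(values.shape), 0.0)
    return SyntheticRecording(
        kind="rate",
        values=values,
        neuron_class=np.array(["RS"] * n_neurons),
        trial_condition=np.array(conds),
        trial_stimulus=np.array(stims),
        windows={"baseline": (0, 10), "evoked": (10, 16)},
        ground_truth={
            "b": b,
            "mu": mu,
            "theta": theta,
            "overlaps": overlaps.tolist(),
            "sparsity_f": sparsity_f,
            "noise_sd": float(noise_sd),
            "seed": seed,
        },
    )


def make_segregated_recording(
    n_neurons: int = 400,
    frac_pe: float = 0.4,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticRecording:
    """SYNTHETIC null: fully segregated functional populations.

    A constructed stand-in for the segregated-populations hypothesis (not a
    model output): each neuron has the *same* Delta sign pattern for the
    expected and probe stimulus (PE neurons suppress their mismatch response
    in the active condition for every stimulus; R neurons never do), so the
    segregation index is 1 up to trial noise.
    """
    rng = np.random.default_rng(seed)
    is_pe = rng.random(n_neurons) < frac_pe
    gain = rng.uniform(1.0, 3.0, size=n_neurons)
    n_bins, n_trials = 16, 20
    blocks, conds, stims = [], [], []
    for s in ("expected", "probe"):
        passive = gain  # responds to both sounds in passive
        active = np.where(is_pe, 0.2 * gain, gain)  # PE suppressed when predicted
        for cnd, resp in (("passive", passive), ("active", active)):
            block = np.zeros((n_trials, n_neurons, n_bins))
            block[:, :, 10:] = resp[None, :, None]
            blocks.append(block)
            conds += [cnd] * n_trials
            stims += [s] * n_trials
    values = np.concatenate(blocks, axis=0)
    if noise_sd > 0:
        values = np.maximum(values + noise_sd * rng.standard_normal(values.shape), 0.0)
    return SyntheticRecording(
        kind="rate",
        values=values,
        neuron_class=np.array(["RS"] * n_neurons),
        trial_condition=np.array(conds),
        trial_stimulus=np.array(stims),
        windows={"baseline": (0, 10), "evoked": (10, 16)},
        ground_truth={"synthetic_null": "segregated", "frac_pe": frac_pe, "seed": seed},
    )


def generate_rsfs_recording(
    ei,
    n_rs: int | None = None,
    n_fs: int | None = None,
    n_trials: int = 20,
    noise_sd: float | None = None,
    baseline_rate: float = 2.0,
    seed: int = 0,
) -> SyntheticRecording:
    """Regular-spiking / fast-spiking recording from an E/I decomposition.

    The underlying network must have pair 0 trained (expected sound +
    movement) and pair 1 untrained (probe sound).  RS rows sample excitatory
    rates, FS rows inhibitory rates; movement trials pair each sound with the
    trained movement (y of pair 0), passive trials present the sound alone.
    Probe-sound correlations are read as "before learning".
    """
    net = ei.net
    if net.P < 2:
        raise ParameterError("rsfs recording needs P >= 2 (expected + probe pairs)")
    rng = np.random.default_rng(seed)
    rates = {}
    for stim_name, k in (("expected", 0), ("probe", 1)):
        x = np.zeros(net.P)
        x[k] = 1.0
        y_pas = np.zeros(net.P)
        y_mov = np.zeros(net.P)
        y_mov[0] = 1.0
        for cond_name, y in (("passive", y_pas), ("active", y_mov)):
            r_E = steady_state(net, StimulusEnsemble(x, y, label=cond_name)).r
            rates[(stim_name, cond_name)] = (r_E, ei.i_rates(r_E))
    if noise_sd is None:
        noise_sd = _default_noise(rates[("expected", "passive")][0])
    n_rs = net.N if n_rs is None else n_rs
    n_fs = ei.N_I if n_fs is None else n_fs
    idx_rs = rng.choice(net.N, size=n_rs, replace=n_rs > net.N)
    idx_fs = rng.choice(ei.N_I, size=n_fs, replace=n_fs > ei.N_I)
    classes = np.array(["RS"] * n_rs + ["FS"] * n_fs)
    n_bins = 16
    blocks, conds, stims = [], [], []
    for stim_name in ("expected", "probe"):
        for cond_name in ("passive", "active"):
            r_E, r_I = rates[(stim_name, cond_name)]
            resp = np.concatenate([r_E[idx_rs], r_I[idx_fs]])
            block = np.full((n_trials, n_rs + n_fs, n_bins), baseline_rate)
            block[:, :, 10:] += resp[None, :, None]
            blocks.append(block)
            conds += [cond_name] * n_trials
            stims += [stim_name] * n_trials
    values = np.concatenate(blocks, axis=0)
    values = np.maximum(values + noise_sd * rng.standard_normal(values.shape), 0.0)
    return SyntheticRecording(
        kind="rate",
        values=values,
        neuron_class=classes,
        trial_condition=np.array(conds),
        trial_stimulus=np.array(stims),
        windows={"baseline": (0, 10), "evoked": (10, 16)},
        ground_truth={
            "lambda_ei": ei.lambda_ei,
            "b": net.params.b,
            "mu": net.weights.mu.tolist(),
            "noise_sd": float(noise_sd),
            "seed": seed,
            "N_model": net.N,
        },
    )
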