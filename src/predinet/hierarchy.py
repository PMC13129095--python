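"""Three-module hierarchical predictive networks (bidirectional and control).

Module M1 receives the x stimulus, M3 the y stimulus, and M2 sits between
them.  Modules exchange P-dimensional codes: module l sends the readout
u^l = V^l.T r^l / N upward and d^l = W^l.T r^l / N downward, so the
effective inter-module couplings are the rank-P composites V^l W^{l+1,T}/N.  In the
*bidirectional* model every module minimizes prediction errors with respect
to both its bottom-up and top-down signals; the joint dynamics

    dh^l/dt = -h^l + b_l ( J^l r^l + W^l a^l + V^l c^l ),
    J^l = -(1/N)(W^l W^l.T + V^l V^l.T),

with a^1 = x, a^l = u^{l-1}; c^3 = y, c^l = d^{l+1}, are the exact gradient
flow of the stacked objective

    E = |x - d^1|^2 + |u^1 - d^2|^2 + |u^2 - d^3|^2 + |u^3 - y|^2
        + sum_l (2/(b_l N)) sum_i F(r^l_i).

The *unidirectional* control instead lets only M2 generate predictions of its
neighbours' activity (embedded back into neuron space), which removes the
V V.T component of J in M1/M3 and adds a -delta_ij self term there; M2 is
unchanged.  Within-module learning is summarized by the correlation mu
between each module's W and V columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .celltypes import classify_pair
from .dynamics import SteadyState, steady_state
from .errors import ConvergenceError, DimensionError, ParameterError
from .network import NetworkParams, RecurrentNetwork, build_connectivity
from .stimuli import StimulusEnsemble, condition
from .weights import MU_TRAINED, FeedforwardWeights, sample_weights

MODES = ("bidirectional", "unidirectional")


@dataclass
class HierarchicalNetwork:
    """Per-module weights plus gains, threshold and prediction mode."""

    weights: list[FeedforwardWeights]   # one per module, each N x P
    gains: tuple[float, float, float]
    mode: str = "bidirectional"
    theta: float = 0.0
    tol: float = 1e-10

    def __post_init__(self):
        if self.mode not in MODES:
            raise ParameterError(f"mode must be one of {MODES}")
        if len(self.weights) != 3:
            raise DimensionError("exactly three modules are supported")
        if any(b <= 0 for b in self.gains):
            raise ParameterError("gains must be positive")
        shapes = {(w.N, w.P) for w in self.weights}
        if len(shapes) != 1:
            raise DimensionError("all modules must share N and P")
        self._nets = self._build_module_nets()

    @property
    def N(self) -> int:
        return self.weights[0].N

    @property
    def P(self) -> int:
        return self.weights[0].P

    @property
    def alpha(self) -> float:
        return self.P / self.N

    def _build_module_nets(self) -> list[RecurrentNetwork]:
        nets = []
        for l, (wl, bl) in enumerate(zip(self.weights, self.gains)):
            params = NetworkParams(b=bl, theta=self.theta, tol=self.tol)
            if self.mode == "unidirectional" and l in (0, 2):
                M = wl.W if l == 0 else wl.V
                J = -(M @ M.T) / wl.N - np.eye(wl.N)
                nets.append(RecurrentNetwork(params=params, weights=wl, pruned=True, _J_dense=J))
            else:
                nets.append(RecurrentNetwork(params=params, weights=wl))
        return nets

    def module_connectivity(self, l: int) -> np.ndarray:
        """Dense within-module connectivity actually used by module l."""
        net = self._nets[l]
        if net._J_dense is not None:
            return net._J_dense
        return build_connectivity(net.weights)

    def feedforward_inputs(self, stim: StimulusEnsemble, rates: list[np.ndarray]):
        """Per-module I^F = W a + V c given the current rates of all modules."""
        if stim.P != self.P:
            raise DimensionError(f"stimulus P={stim.P}, network P={self.P}")
        N = self.N
        w1, w2, w3 = self.weights
        up1 = w1.V.T @ rates[0] / N
        up2 = w2.V.T @ rates[1] / N
        down2 = w2.W.T @ rates[1] / N
        down3 = w3.W.T @ rates[2] / N
        return [
            w1.W @ stim.x + w1.V @ down2,
            w2.W @ up1 + w2.V @ down3,
            w3.W @ up2 + w3.V @ stim.y,
        ]


@dataclass
class HierSteadyState:
    states: list[SteadyState]
    residual: float
    sweeps: int

    def rates(self, l: int) -> np.ndarray:
        return self.states[l].r

    def voltages(self, l: int) -> np.ndarray:
        return self.states[l].h


def build_hier(
    N: int,
    P: int,
    gains,
    mu,
    mode: str = "bidirectional",
    seed: int = 0,
    theta: float = 0.0,
    mu_modules=None,
) -> HierarchicalNetwork:
    """Sample a three-module network.

    ``mu`` applies to every module's (W, V) pair unless ``mu_modules`` gives
    per-module values (e.g. to confine learning to a single interface).
    """
    mus = [mu] * 3 if mu_modules is None else list(mu_modules)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)]
    ws = [sample_weights(N, P, m, s) for m, s in zip(mus, seeds)]
    return HierarchicalNetwork(weights=ws, gains=tuple(gains), mode=mode, theta=theta)


def hier_steady_state(
    hnet: HierarchicalNetwork,
    stim: StimulusEnsemble,
    max_sweeps: int = 300,
    h0: list[np.ndarray] | None = None,
) -> HierSteadyState:
    """Joint fixed point by block-coordinate solves of the three modules.

    For the bidirectional model this is exact alternating minimization of the
    jointly convex stacked objective, so it converges to the unique optimum.
    """
    N = hnet.N
    states: list[SteadyState | None] = [None] * 3
    rates = [np.zeros(N) for _ in range(3)]
    hs = [np.zeros(N) for _ in range(3)] if h0 is None else [h.copy() for h in h0]
    tol = hnet.tol
    for sweep in range(1, max_sweeps + 1):
        for l in range(3):
            IF = hnet.feedforward_inputs(stim, rates)[l]
            states[l] = steady_state(hnet._nets[l], IF=IF, h0=hs[l])
            rates[l] = states[l].r
            hs[l] = states[l].h
        IFs = hnet.feedforward_inputs(stim, rates)
        res = 0.0
        scale = 1.0
        for l in range(3):
            net = hnet._nets[l]
            rhs = -hs[l] + net.params.b * (net.recurrent_drive(rates[l]) + IFs[l])
            res = max(res, float(np.max(np.abs(rhs))))
            scale = max(scale, net.params.b * float(np.max(np.abs(IFs[l]))))
        if res <= tol * scale:
            return HierSteadyState(states=states, residual=res, sweeps=sweep)
    raise ConvergenceError(
        f"hierarchical steady state did not converge (residual {res:.3e})"
    )


def hier_energy(hnet: HierarchicalNetwork, rates, stim: StimulusEnsemble) -> float:
    """Stacked bidirectional objective (prediction errors + efficiency)."""
    N = hnet.N
    w1, w2, w3 = hnet.weights
    d1 = w1.W.T @ rates[0] / N
    u1 = w1.V.T @ rates[0] / N
    d2 = w2.W.T @ rates[1] / N
    u2 = w2.V.T @ rates[1] / N
    d3 = w3.W.T @ rates[2] / N
    u3 = w3.V.T @ rates[2] / N
    e = (
        np.sum((stim.x - d1) ** 2)
        + np.sum((u1 - d2) ** 2)
        + np.sum((u2 - d3) ** 2)
        + np.sum((u3 - stim.y) ** 2)
    )
    for r, b in zip(rates, hnet.gains):
        e += np.sum((r + hnet.theta) ** 2) / (b * N)
    return float(e)


def simulate_hier(
    hnet: HierarchicalNetwork,
    stim,
    T: float,
    dt: float = 0.01,
    record_dt: float | None = None,
):
    """Joint explicit-Euler integration; returns (times, [H1, H2, H3])."""
    static = isinstance(stim, StimulusEnsemble)
    N = hnet.N
    hs = [np.zeros(N) for _ in range(3)]
    n_steps = int(np.ceil(T / dt))
    every = max(1, int(round((record_dt or dt) / dt)))
    times = [0.0]
    Hs = [[h.copy()] for h in hs]
    for k in range(1, n_steps + 1):
        t = k * dt
        st = stim if static else stim(t - dt)
        rates = [np.maximum(h - hnet.theta, 0.0) for h in hs]
        IFs = hnet.feedforward_inputs(st, rates)
        for l in range(3):
            net = hnet._nets[l]
            hs[l] = hs[l] + dt * (
                -hs[l] + net.params.b * (net.recurrent_drive(rates[l]) + IFs[l])
            )
        if k % every == 0 or k == n_steps:
            times.append(t)
            for l in range(3):
                Hs[l].append(hs[l].copy())
    return np.asarray(times), [np.asarray(H) for H in Hs]


def _module_condition_voltages(hnet, pair: int):
    ss_x = hier_steady_state(hnet, condition(hnet.P, "x_only", pair=pair))
    ss_m = hier_steady_state(hnet, condition(hnet.P, "match", pair=pair))
    return ss_x, ss_m


def calibrate_gains(
    N: int,
    P: int,
    mu: float,
    mismatch_floor: float,
    pe_target: float,
    b2_grid=None,
    b13_grid=None,
    seed: int = 0,
    pe_tol: float = 0.05,
) -> tuple[float, float, float]:
    """Choose (b1, b2, b3) on the constraint manifold.

    For each candidate b2, the smallest symmetric gain b1 = b3 meeting the
    M2 mismatch-rate floor is found (mismatch responses increase with each
    gain); among those, the b2 whose after-learning M2 PE fraction is closest
    to ``pe_target`` (the single-module value) is selected.
    """
    if b2_grid is None:
        b2_grid = np.logspace(np.log10(0.5), np.log10(50), 7)
    if b13_grid is None:
        b13_grid = np.logspace(np.log10(0.5), np.log10(50), 7)
    if mismatch_floor <= 0:
        warnings.warn("degenerate mismatch floor <= 0: returning smallest grid point")
        return float(b13_grid[0]), float(b2_grid[0]), float(b13_grid[0])
    best = None
    for b2 in b2_grid:
        feasible_b13 = None
        for b13 in b13_grid:
            hnet = build_hier(N, P, (b13, b2, b13), mu, seed=seed)
            ss_x = hier_steady_state(hnet, condition(P, "x_only", pair=0))
            if ss_x.rates(1).mean() >= mismatch_floor:
                feasible_b13 = b13
                break
        if feasible_b13 is None:
            continue
        hnet = build_hier(N, P, (feasible_b13, b2, feasible_b13), mu, seed=seed)
        ss_x, ss_m = _module_condition_voltages(hnet, 0)
        hx, hm = ss_x.voltages(1), ss_m.voltages(1)
        sigma = float(np.std(hx - hx.mean()))
        tab = classify_pair(hx, hm, sigma, center=True)
        pe = float((tab["label"] == "PE").mean())
        gap = abs(pe - pe_target)
        if best is None or gap < best[0]:
            best = (gap, (float(feasible_b13), float(b2), float(feasible_b13)), pe)
    if best is None:
        raise ParameterError(
            f"no feasible gains on the scanned grids (floor {mismatch_floor:g})"
        )
    if best[0] > pe_tol:
        warnings.warn(
            f"M2 PE fraction {best[2]:.3f} misses target {pe_target:.3f} "
            f"by more than {pe_tol}"
        )
    return best[1]


def module_metrics(
    N: int,
    P: int,
    gains,
    mus,
    mode: str = "bidirectional",
    seed: int = 0,
    pair: int = 0,
):
    """Per-module mismatch/match ratio and R/PE fractions across learning."""
    import pandas as pd

    sigmas = None
    ref = build_hier(N, P, gains, MU_TRAINED, mode=mode, seed=seed)
    ss_ref, _ = _module_condition_voltages(ref, pair)
    sigmas = [float(np.std(ss_ref.voltages(l) - ss_ref.voltages(l).mean())) for l in range(3)]
    rows = []
    for mu in mus:
        hnet = build_hier(N, P, gains, mu, mode=mode, seed=seed)
        ss_x, ss_m = _module_condition_voltages(hnet, pair)
        for l in range(3):
            hx, hm = ss_x.voltages(l), ss_m.voltages(l)
            tab = classify_pair(hx, hm, sigmas[l], center=True)
            match_rate = ss_m.rates(l).mean()
            rows.append(
                {
                    "module": l + 1,
                    "mu": mu,
                    "mismatch_rate": float(ss_x.rates(l).mean()),
                    "match_rate": float(match_rate),
                    "ratio": float(ss_x.rates(l).mean() / match_rate)
                    if match_rate > 0
                    else np.inf,
                    "frac_R": float((tab["label"] == "R").mean()),
                    "frac_PE": float((tab["label"] == "PE").mean()),
                }
            )
    return pd.DataFrame(rows)


def module_balance(hnet: HierarchicalNetwork, stim: StimulusEnsemble):
    """Median per-module balance |b_l I^F_i / h_i| at the joint steady state."""
    ss = hier_steady_state(hnet, stim)
    IFs = hnet.feedforward_inputs(stim, [ss.rates(l) for l in range(3)])
    medians = []
    for l in range(3):
        h = ss.voltages(l)
        mask = np.abs(h) > 1e-8
        B = np.abs(hnet.gains[l] * IFs[l][mask] / h[mask])
        medians.append(float(np.median(B)))
    return medians


def mixed_and_balance_vs_alpha(
    N: int,
    alphas,
    gains,
    mu: float = MU_TRAINED,
    mode: str = "bidirectional",
    seed: int = 0,
):
    """Mixed-representation fraction and median balance per module vs alpha."""
    import pandas as pd

    rows = []
    for alpha in alphas:
        P = max(2, int(round(alpha * N)))
        hnet = build_hier(N, P, gains, mu, mode=mode, seed=seed)
        ss_x1 = hier_steady_state(hnet, condition(P, "x_only", pair=0))
        ss_m1 = hier_steady_state(hnet, condition(P, "match", pair=0))
        ss_x2 = hier_steady_state(hnet, condition(P, "x_only", pair=1))
        ss_m2 = hier_steady_state(hnet, condition(P, "match", pair=1))
        balances = module_balance(hnet, condition(P, "match", pair=0))
        for l in range(3):
            hx1, hm1 = ss_x1.voltages(l), ss_m1.voltages(l)
            hx2, hm2 = ss_x2.voltages(l), ss_m2.voltages(l)
            sigma = float(np.std(hx1 - hx1.mean()))
            t1 = classify_pair(hx1, hm1, sigma, center=True)
            t2 = classify_pair(hx2, hm2, sigma, center=True)
            dually = (t1["responsive"] & t2["responsive"]).to_numpy()
            if dually.sum() == 0:
                mixed = np.nan
            else:
                l1 = t1["label"].to_numpy()[dually]
                l2 = t2["label"].to_numpy()[dually]
                mixed = float(
                    np.mean(((l1 == "R") & (l2 == "PE")) | ((l1 == "PE") & (l2 == "R")))
                )
            rows.append(
                {
                    "module": l + 1,
                    "alpha": alpha,
                    "mixed_fraction": mixed,
                    "n_dually": int(dually.sum()),
                    "balance_median": balances[l],
                }
            )
    return pd.DataFrame(rows)


def crossmodal_decoding(
    N: int,
    P: int,
    gains,
    mu: float,
    seed: int = 0,
    noise_sd: float = 0.5,
    n_samples: int = 60,
    module: int = 3,
) -> dict:
    """Decode x-stimulus identity from one module's rates, in both modes.

    Matched weights across modes (same seed); x-only conditions for each of
    the P pairs; multiclass linear decoder on noise-corrupted steady rates.
    Returns held-out accuracy for the bidirectional and unidirectional model.
    """
    from sklearn.model_selection import train_test_split
    from sklearn.svm import LinearSVC

    out = {}
    for mode in MODES:
        hnet = build_hier(N, P, gains, mu, mode=mode, seed=seed)
        protos = []
        for k in range(P):
            ss = hier_steady_state(hnet, condition(P, "x_only", pair=k))
            protos.append(ss.rates(module - 1))
        rng = np.random.default_rng(seed + 1)
        X, y = [], []
        for i in range(n_samples):
            k = i % P
            X.append(np.maximum(protos[k] + noise_sd * rng.standard_normal(N), 0.0))
            y.append(k)
        X, y = np.asarray(X), np.asarray(y)
        Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=0.5, random_state=seed, stratify=y)
        clf = LinearSVC(dual="auto").fit(Xtr, ytr)
        out[mode] = float(np.mean(clf.predict(Xte) == yte))
    return out
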