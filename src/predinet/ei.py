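"""Dale-compliant excitatory/inhibitory decompositions of the network.

The single-population network does not respect Dale's law.  It is embedded in
an E/I network

    dh^E/dt      = -h^E + J^EE r^E - J^EI r^I + I^E,
    tau_I dh^I/dt = -h^I + J^IE r^E - J^II r^I + I^I,

(inhibitory matrices stored as nonnegative magnitudes; phi_I = ReLU with zero
threshold) whose excitatory steady state reproduces the original network
exactly.  With J^II = 0 the matching constraints reduce to

    J^EE - J^EI J^IE = b J,      I^E - J^EI I^I = b I^F,

which leave a one-parameter family of solutions, indexed by lambda_EI:

* lambda_EI = 0 -- *private inhibition*: J^IE = I, each I neuron copies its
  parent E neuron, and J^EI is the rectified negative part of bJ.
* lambda_EI = 1 -- *inhibitory internal predictions*: every I neuron pools
  excitation through a nonnegatively shifted stimulus weight vector, so its
  rate is an exact linear combination of one internal prediction (x_hat or
  y_hat) and the population mean rate.
* intermediate lambda -- each I neuron mixes its private input with one
  prediction channel: row i of J^IE is (1-lambda) e_i + lambda p_k(i).

J^EI is chosen so that J^EE = bJ + J^EI J^IE is entrywise nonnegative, making
the matching constraints hold *identically* (zero residual by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .celltypes import classify_pair, pearson
from .dynamics import steady_state
from .errors import ConvergenceError, InsufficientDataError, ParameterError
from .network import NetworkParams, RecurrentNetwork, build_connectivity, make_network
from .stimuli import StimulusEnsemble, condition
from .weights import MU_TRAINED


@dataclass
class EINetwork:
    """The four connectivity blocks plus the interpolation parameter.

    ``J_EI`` and ``J_II`` store magnitudes of inhibitory synapses (delivered
    current is minus these).
    """

    J_EE: np.ndarray
    J_EI: np.ndarray       # N_E x N_I, >= 0 (magnitudes)
    J_IE: np.ndarray       # N_I x N_E, >= 0
    lambda_ei: float
    tau_I: float
    net: RecurrentNetwork  # the matched single-population network
    assignments: np.ndarray  # prediction-channel index of each I neuron
    J_II: np.ndarray | None = None  # None means zero

    @property
    def N_E(self) -> int:
        return self.J_EE.shape[0]

    @property
    def N_I(self) -> int:
        return self.J_IE.shape[0]

    def external_inputs(self, stim: StimulusEnsemble):
        """(I^E, I^I) realizing the matching constraint for one condition."""
        b = self.net.params.b
        return b * self.net.feedforward(stim), np.zeros(self.N_I)

    def constraint_residuals(self) -> tuple[float, float]:
        """Max-norm residuals of the two matching constraints."""
        bJ = self.net.params.b * build_connectivity(
            self.net.weights, self.net.params.exclude_diagonal
        )
        res_J = float(np.max(np.abs(self.J_EE - self.J_EI @ self.J_IE - bJ)))
        # I^E - J_EI I^I - b I^F = 0 identically since I^I = 0 and I^E = b I^F
        return res_J, 0.0

    def effective_network(self) -> RecurrentNetwork:
        """Single-population network with J = (J^EE - J^EI J^IE)/b.

        Solving this network's steady state *from the E/I blocks alone* gives
        the E-population steady state of the two-population system (the I
        population is slaved: h^I = J^IE r^E >= 0, so phi_I is the identity
        there).
        """
        J_eff = (self.J_EE - self.J_EI @ self.J_IE) / self.net.params.b
        return RecurrentNetwork(
            params=self.net.params, weights=self.net.weights, pruned=True, _J_dense=J_eff
        )

    def i_rates(self, r_E: np.ndarray) -> np.ndarray:
        """Steady-state inhibitory rates given excitatory rates."""
        h_I = self.J_IE @ r_E
        return np.maximum(h_I, 0.0)


def _prediction_rows(weights, b: float) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative prediction channels (rows of J^IE) and J^EI columns.

    For each pair and modality, the channel pools through u = w + max|w| * 1
    (>= 0); one extra global channel pools through
    q = sum_k m_k (m_k 1 - w_k) >= 0.  The normalizations are chosen so a
    channel's rate is on the scale of the population mean rate and so that
    (columns) x (rows) reconstructs the exact compensation term.
    """
    N = weights.N
    cols, rows = [], []
    q = np.zeros(N)
    for M in (weights.W, weights.V):
        for k in range(M.shape[1]):
            w = M[:, k]
            m = float(np.max(np.abs(w)))
            u = w + m
            rows.append(u / N)   # channel rate = x_hat + m * mean rate
            cols.append(b * u)
            q += m * (m - w)
    rows.append(q / N)
    cols.append(b * np.ones(N))
    return np.array(rows), np.array(cols).T  # (2P+1, N), (N, 2P+1)


def decompose(
    net: RecurrentNetwork,
    lambda_ei: float,
    N_I: int | None = None,
    seed: int = 0,
    tau_I: float = 0.5,
) -> EINetwork:
    """Construct the E/I network at one point of the lambda_EI continuum."""
    if not 0 <= lambda_ei <= 1:
        raise ParameterError(f"lambda_ei must lie in [0, 1], got {lambda_ei}")
    if net.pruned:
        raise ParameterError("decompose requires the unpruned Gram connectivity")
    N = net.N
    if N_I is None:
        N_I = N
    b = net.params.b
    lam = float(lambda_ei)
    bJ = b * build_connectivity(net.weights, net.params.exclude_diagonal)
    A_priv_full = np.maximum(-bJ, 0.0)  # rectified inhibitory part of bJ
    p_rows, a_cols = _prediction_rows(net.weights, b)
    n_chan = p_rows.shape[0]
    rng = np.random.default_rng(seed)
    assignments = rng.permutation(np.arange(N_I) % n_chan)
    counts = np.bincount(assignments, minlength=n_chan).astype(float)
    # The channel normalization is a free parameter of the family (it cancels
    # in J_EI @ J_IE).  Fix it so the across-I-neuron variance of the channel
    # rates matches the private (parent-copy) rate variance in a reference
    # condition, which spreads the private->prediction transition over the
    # whole lambda range.
    r_ref = steady_state(net, condition(net.P, "x_only", pair=0)).r
    chan_vals = (p_rows @ r_ref)[assignments]
    v_chan, v_priv = float(np.var(chan_vals)), float(np.var(r_ref))
    kappa = np.sqrt(v_priv / v_chan) if v_chan > 0 else 1.0
    p_rows = kappa * p_rows
    a_cols = a_cols / kappa

    # J^IE rows: private part (identity pattern, only meaningful at N_I = N)
    B = lam * p_rows[assignments]
    if lam < 1:
        if N_I != N:
            raise ParameterError("intermediate lambda requires N_I == N_E")
        B[np.arange(N), np.arange(N)] += 1 - lam
    # J^EI columns, scaled so J^EE = bJ + A B is entrywise nonnegative
    s = 1.0 / ((1 - lam) ** 2 + lam**2)
    A = s * lam * (a_cols[:, assignments] / counts[assignments])
    if lam < 1:
        A += s * (1 - lam) * A_priv_full
    J_EE = bJ + A @ B
    worst = float(J_EE.min())
    if worst < -1e-8 * max(1.0, float(np.abs(bJ).max())):
        raise ConvergenceError(
            f"E/I decomposition failed: J_EE has negative entries (min {worst:.3e})"
        )
    # float rounding can leave tiny negatives
    np.clip(J_EE, 0.0, None, out=J_EE)
    return EINetwork(
        J_EE=J_EE, J_EI=A, J_IE=B, lambda_ei=lam, tau_I=tau_I, net=net,
        assignments=assignments,
    )


def i_sigma(ei: EINetwork, pair: int = 0) -> float:
    """Classification scale for I neurons: std of centered h^I, x-only."""
    r_E = steady_state(ei.net, condition(ei.net.P, "x_only", pair=pair)).r
    h_I = ei.J_IE @ r_E
    return float(np.std(h_I - h_I.mean()))


@dataclass
class InhibitoryGeometry:
    cos_psi: float        # cos(r^I_xy, r^I_x): match vs x-only mismatch
    cos_theta: float      # cos(r^I_x, r^I_y): the two mismatch responses
    cos_psi_prime: float  # cos(r^I_xy, r^I_y)
    frac_R: float         # centered-criterion R fraction among I neurons
    e_geometry: "InhibitoryGeometry | None" = None


def _centered_cos(a, b):
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ParameterError("zero-norm response vector; angle undefined")
    return float(a @ b / (na * nb))


def inhibitory_geometry(
    ei: EINetwork,
    pair: int = 0,
    sigma_i: float | None = None,
) -> InhibitoryGeometry:
    """Angle statistics of inhibitory population responses for one pair.

    ``sigma_i`` is the I-population classification scale; when omitted it is
    computed from this network (appropriate when mu = 0.97).
    """
    ss = {
        lab: steady_state(ei.net, condition(ei.net.P, lab, pair=pair))
        for lab in ("x_only", "y_only", "match")
    }
    rI = {lab: ei.i_rates(s.r) for lab, s in ss.items()}
    if sigma_i is None:
        sigma_i = i_sigma(ei, pair=pair)
    hI_x = ei.J_IE @ ss["x_only"].r
    hI_xy = ei.J_IE @ ss["match"].r
    tab = classify_pair(hI_x, hI_xy, sigma_i, center=True)
    eg = InhibitoryGeometry(
        cos_psi=_centered_cos(ss["match"].r, ss["x_only"].r),
        cos_theta=_centered_cos(ss["x_only"].r, ss["y_only"].r),
        cos_psi_prime=_centered_cos(ss["match"].r, ss["y_only"].r),
        frac_R=float("nan"),
    )
    return InhibitoryGeometry(
        cos_psi=_centered_cos(rI["match"], rI["x_only"]),
        cos_theta=_centered_cos(rI["x_only"], rI["y_only"]),
        cos_psi_prime=_centered_cos(rI["match"], rI["y_only"]),
        frac_R=float((tab["label"] == "R").mean()),
        e_geometry=eg,
    )


def weight_change_analysis(
    ei_before: EINetwork,
    ei_after: EINetwork,
    pair: int = 0,
    zero_tol_frac: float = 1e-3,
) -> dict:
    """I-to-E synaptic weight distributions before vs after learning.

    Both networks must share lambda_EI and seed; "before" is mu = 0 and
    "after" the trained correlation.  Returns overall and class-conditioned
    (I class -> E class) weight samples plus per-E-neuron totals.
    """
    if ei_before.lambda_ei != ei_after.lambda_ei:
        raise ParameterError("compare decompositions at the same lambda_EI")
    out = {"lambda_ei": ei_before.lambda_ei}
    for tag, ei in (("before", ei_before), ("after", ei_after)):
        A = ei.J_EI
        out[f"weights_{tag}"] = A.ravel()
        out[f"total_per_E_{tag}"] = A.sum(axis=1)
        out[f"sparsity_{tag}"] = float(np.mean(A <= zero_tol_frac * A.max()))
        # functional classes of E and I neurons for the conditioning
        ssx = steady_state(ei.net, condition(ei.net.P, "x_only", pair=pair))
        ssm = steady_state(ei.net, condition(ei.net.P, "match", pair=pair))
        sig_e = float(np.std(ssx.h - ssx.h.mean()))
        e_lab = classify_pair(ssx.h, ssm.h, sig_e, center=True)["label"].to_numpy()
        hIx, hIm = ei.J_IE @ ssx.r, ei.J_IE @ ssm.r
        sig_i = float(np.std(hIx - hIx.mean()))
        i_lab = classify_pair(hIx, hIm, sig_i, center=True)["label"].to_numpy()
        rr = A[np.ix_(e_lab == "R", i_lab == "R")]
        pe_to = A[np.ix_(np.isin(e_lab, ["R", "PE"]), i_lab == "PE")]
        out[f"R_to_R_{tag}"] = rr.ravel()
        out[f"PE_to_RPE_{tag}"] = pe_to.ravel()
    return out


def rsfs_correlations(recording) -> dict:
    """Movement-vs-passive population correlations per class and stimulus.

    Returns {(class, stimulus): Pearson r} with stimulus 'probe' read as
    before learning and 'expected' as after learning.
    """
    out = {}
    for cls in ("RS", "FS"):
        mask = recording.neuron_class == cls
        if mask.sum() < 3:
            raise InsufficientDataError(f"fewer than 3 {cls} neurons in recording")
        for stim in ("expected", "probe"):
            mov = recording.response_change(stim, "active")[mask]
            pas = recording.response_change(stim, "passive")[mask]
            out[(cls, stim)] = pearson(mov, pas)
    return out


def model_rsfs_correlations(
    lambda_ei: float,
    b: float,
    N: int = 300,
    seed: int = 0,
    mu_trained: float = MU_TRAINED,
) -> dict:
    """Noise-free model analogue of ``rsfs_correlations``.

    Pair 0 is the trained (expected) association; pair 1 an untrained probe.
    Movement pairs the sound with the trained movement (y of pair 0).
    """
    net = make_network(N=N, P=2, mu=[mu_trained, 0.0], b=b, seed=seed)
    ei = decompose(net, lambda_ei, seed=seed)
    out = {}
    for stim_name, k in (("expected", 0), ("probe", 1)):
        x = np.zeros(2)
        y = np.zeros(2)
        x[k] = 1.0
        pas = steady_state(net, StimulusEnsemble(x, y.copy(), label="passive"))
        y_mov = y.copy()
        y_mov[0] = 1.0
        mov = steady_state(net, StimulusEnsemble(x, y_mov, label="movement"))
        out[("RS", stim_name)] = pearson(mov.r, pas.r)
        out[("FS", stim_name)] = pearson(ei.i_rates(mov.r), ei.i_rates(pas.r))
    return out


def estimate_lambda(
    recording,
    b: float,
    lambda_grid=None,
    N_ref: int = 300,
    n_ref_seeds: int = 2,
    seed: int = 0,
) -> dict:
    """Estimate lambda_EI by matching RS/FS correlations to model curves.

    The four data correlations (RS/FS x expected/probe) are compared with the
    model's curves over a lambda grid (averaged over reference network
    instances); the grid argmin of the squared distance is returned.
    """
    if lambda_grid is None:
        lambda_grid = np.linspace(0.0, 1.0, 21)
    data = rsfs_correlations(recording)
    keys = sorted(data)
    target = np.array([data[k] for k in keys])
    losses = []
    for lam in lambda_grid:
        per_seed = []
        for s in range(n_ref_seeds):
            m = model_rsfs_correlations(lam, b, N=N_ref, seed=seed + 7919 * s)
            per_seed.append([m[k] for k in keys])
        model = np.mean(per_seed, axis=0)
        losses.append(float(np.sum((model - target) ** 2)))
    losses = np.asarray(losses)
    i = int(np.argmin(losses))
    return {
        "lambda_hat": float(lambda_grid[i]),
        "grid": np.asarray(lambda_grid),
        "loss": losses,
        "data_correlations": data,
    }
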