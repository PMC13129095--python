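"""The recurrent rate network and its normative objective.

Dynamics (time in units of the membrane constant):

    dh_i/dt = -h_i + b * ( sum_j J_ij phi(h_j) + I^F_i(x, y) ),
    r_i = phi(h_i) = max(h_i - theta, 0),

with the prescribed connectivity and feedforward input

    J    = -(1/N) (W W^T + V V^T),
    I^F  = W x + V y.

The common gain ``b`` trades off prediction accuracy against encoding cost.
With the linear readouts  x_hat^k = w^k . r / N,  y_hat^k = v^k . r / N,
the fixed point of the dynamics is exactly the minimizer over r >= 0 of the
convex objective

    E(r) = sum_k [ (x^k - x_hat^k)^2 + (y^k - y_hat^k)^2 ]
           + (2 / (b N)) sum_i F(r_i),          F(r) = (r + theta)^2 / 2,

i.e. squared multimodal prediction-errors plus a per-neuron (intensive)
encoding-efficiency penalty, and the dynamics are a gradient flow of E.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DimensionError, ParameterError
from .stimuli import StimulusEnsemble
from .weights import FeedforwardWeights


@dataclass(frozen=True)
class NetworkParams:
    """Scalar parameters of the rate network."""

    b: float = 2.0            # gain; larger b -> tighter prediction, higher rates
    theta: float = 0.0        # ReLU threshold (voltage units)
    dt: float = 0.01          # default Euler step, membrane-constant units
    tol: float = 1e-10        # max-norm residual tolerance for steady states
    max_iter: int = 100_000
    exclude_diagonal: bool = False  # drop self-couplings of the Gram construction

    def __post_init__(self):
        if self.b <= 0:
            raise ParameterError(f"gain b must be positive, got {self.b}")
        if self.theta < 0:
            raise ParameterError(f"threshold theta must be >= 0, got {self.theta}")


def build_connectivity(weights: FeedforwardWeights, exclude_diagonal: bool = False) -> np.ndarray:
    """Dense connectivity J = -(1/N)(W W^T + V V^T); symmetric, rank <= 2P, NSD."""
    U = weights.stacked()
    J = -(U @ U.T) / weights.N
    if exclude_diagonal:
        np.fill_diagonal(J, 0.0)
    return J


def feedforward_input(weights: FeedforwardWeights, stim: StimulusEnsemble) -> np.ndarray:
    """I^F = W x + V y (the gain b is applied in the dynamics, not here)."""
    if stim.P != weights.P:
        raise DimensionError(f"stimulus has P={stim.P}, weights have P={weights.P}")
    return weights.W @ stim.x + weights.V @ stim.y


@dataclass
class RecurrentNetwork:
    """A single-population predictive-processing network.

    The connectivity is kept in low-rank form (products go through U = [W V])
    unless the network has been pruned, in which case a dense, generally
    asymmetric matrix is stored.
    """

    params: NetworkParams
    weights: FeedforwardWeights
    pruned: bool = False
    _J_dense: np.ndarray | None = field(default=None, repr=False)

    @property
    def N(self) -> int:
        return self.weights.N

    @property
    def P(self) -> int:
        return self.weights.P

    @property
    def alpha(self) -> float:
        """Stimulus load P/N."""
        return self.P / self.N

    @property
    def J(self) -> np.ndarray:
        """Dense connectivity (materialized on demand for unpruned networks)."""
        if self._J_dense is None:
            self._J_dense = build_connectivity(self.weights, self.params.exclude_diagonal)
        return self._J_dense

    def recurrent_drive(self, r: np.ndarray) -> np.ndarray:
        """J @ r, using the low-rank factorization when possible."""
        if self.pruned or self.params.exclude_diagonal or self._J_dense is not None:
            return self.J @ r
        U = self.weights.stacked()
        return -(U @ (U.T @ r)) / self.N

    def feedforward(self, stim: StimulusEnsemble) -> np.ndarray:
        return feedforward_input(self.weights, stim)

    def phi(self, h: np.ndarray) -> np.ndarray:
        return np.maximum(h - self.params.theta, 0.0)

    def readouts(self, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Internal predictions (x_hat, y_hat) as linear readouts of the rates."""
        return self.weights.W.T @ r / self.N, self.weights.V.T @ r / self.N

    def gram_norm(self) -> float:
        """Largest eigenvalue of -J (= ||U^T U||_2 / N), for stability bounds."""
        U = self.weights.stacked()
        if self.pruned or self.params.exclude_diagonal:
            return float(np.linalg.norm(self.J, 2))
        G = U.T @ U / self.N
        return float(np.linalg.eigvalsh(G)[-1])


def make_network(
    N: int,
    P: int,
    mu,
    b: float,
    seed: int,
    theta: float = 0.0,
    **param_kwargs,
) -> RecurrentNetwork:
    """Convenience constructor: sample weights and wrap them in a network."""
    from .weights import sample_weights

    params = NetworkParams(b=b, theta=theta, **param_kwargs)
    return RecurrentNetwork(params=params, weights=sample_weights(N, P, mu, seed))


def energy(net: RecurrentNetwork, r: np.ndarray, stim: StimulusEnsemble) -> float:
    """The convex objective E(r) whose minimizer is the steady state."""
    r = np.asarray(r, dtype=float)
    if r.shape != (net.N,):
        raise DimensionError(f"r must have shape ({net.N},), got {r.shape}")
    if np.any(r < 0):
        raise ParameterError("rates must be nonnegative (r = phi(h) >= 0)")
    x_hat, y_hat = net.readouts(r)
    pred_err = float(np.sum((stim.x - x_hat) ** 2) + np.sum((stim.y - y_hat) ** 2))
    theta = net.params.theta
    efficiency = float(np.sum((r + theta) ** 2)) / (net.params.b * net.N)
    return pred_err + efficiency


def energy_gradient(net: RecurrentNetwork, r: np.ndarray, stim: StimulusEnsemble) -> np.ndarray:
    """dE/dr; zero on the active set at the steady state."""
    x_hat, y_hat = net.readouts(r)
    drive = net.weights.W @ (stim.x - x_hat) + net.weights.V @ (stim.y - y_hat)
    return (2.0 / net.N) * ((r + net.params.theta) / net.params.b - drive)


def prune(net: RecurrentNetwork, keep_prob: float, seed: int) -> RecurrentNetwork:
    """Randomly remove off-diagonal synapses, rescaling survivors by 1/keep_prob.

    Pruning breaks the symmetry of J; the result is returned as a dense-matrix
    network flagged ``pruned``.
    """
    if not 0 < keep_prob <= 1:
        raise ParameterError(f"keep_prob must be in (0, 1], got {keep_prob}")
    J = build_connectivity(net.weights, net.params.exclude_diagonal)
    if keep_prob < 1:
        rng = np.random.default_rng(seed)
        mask = rng.random(J.shape) < keep_prob
        np.fill_diagonal(mask, True)  # self-couplings are part of the construction
        J = np.where(mask, J / keep_prob, 0.0)
        np.fill_diagonal(J, np.diag(build_connectivity(net.weights, net.params.exclude_diagonal)))
    return RecurrentNetwork(params=net.params, weights=net.weights, pruned=keep_prob < 1, _J_dense=J)
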