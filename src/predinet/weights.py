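"""Feedforward weight vectors and their learning-stage statistics.

Each stimulus-pair ``k`` enters the network through two N-dimensional weight
vectors ``w^k`` (x modality) and ``v^k`` (y modality).  Associative learning is
summarized by a single correlation parameter per pair: component-wise the
weights are jointly Gaussian with

    <w_i^k> = <v_i^k> = 0,   <(w_i^k)^2> = <(v_i^k)^2> = 1,
    <w_i^k v_i^k> = mu^k,

with independent draws across pairs and neurons.  ``mu = 0`` is the untrained
state; ``mu -> 1`` a fully learned association.  ``mu = 0.97`` is used as the
after-training value when comparing to data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

#: correlation of a fully trained pair when fitting to data
MU_TRAINED = 0.97


@dataclass(frozen=True)
class FeedforwardWeights:
    """Sampled weight matrices W, V (N x P; columns w^k, v^k) and their mu."""

    W: np.ndarray
    V: np.ndarray
    mu: np.ndarray
    seed: int | None = None

    @property
    def N(self) -> int:
        return self.W.shape[0]

    @property
    def P(self) -> int:
        return self.W.shape[1]

    def stacked(self) -> np.ndarray:
        """The N x 2P matrix U = [W V] used in low-rank connectivity products."""
        return np.concatenate([self.W, self.V], axis=1)


def sample_weights(N: int, P: int, mu, seed: int) -> FeedforwardWeights:
    """Draw the feedforward weights for ``P`` pairs at learning stage(s) ``mu``.

    Parameters
    ----------
    mu : float or sequence of length P
        Within-pair correlation(s), each in [0, 1].
    seed : int
        Seeds a dedicated ``numpy`` generator; equal seeds give identical draws.
    """
    if N < 2 or P < 1:
        raise ParameterError(f"need N >= 2 and P >= 1, got N={N}, P={P}")
    mu_vec = np.broadcast_to(np.asarray(mu, dtype=float), (P,)).copy()
    if np.any(mu_vec < 0) or np.any(mu_vec > 1):
        raise ParameterError(f"mu must lie in [0, 1], got {mu_vec}")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal((N, P))
    z2 = rng.standard_normal((N, P))
    W = z1
    V = mu_vec * z1 + np.sqrt(1.0 - mu_vec**2) * z2
    return FeedforwardWeights(W=W, V=V, mu=mu_vec, seed=seed)
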