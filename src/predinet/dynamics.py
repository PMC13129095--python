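"""Time integration and steady states of the rate dynamics.

The steady state of the network for a static stimulus is the unique minimizer
of the strictly convex objective ``network.energy`` over nonnegative rates,
which is equivalent to the fixed-point (KKT) system

    h_i = b (J phi(h) + I^F)_i         for every neuron,
    r_i = phi(h_i) = max(h_i - theta, 0).

The primary solver is an active-set Newton iteration: given a guess of the set
A = {i : h_i > theta}, the fixed point restricted to A is linear and is solved
exactly (via a Woodbury identity in the 2P-dimensional weight space, or by
conjugate gradients when 2P is large); the set is then refreshed.  Fallbacks
are convex energy minimization (L-BFGS-B) and a damped Picard iteration with a
spectrally safe damping factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.sparse.linalg

from .errors import ConvergenceError, IntegrationError, ParameterError
from .network import RecurrentNetwork, energy, energy_gradient
from .stimuli import StimulusEnsemble


@dataclass(frozen=True)
class NetworkState:
    """Voltages and rates at one time point."""

    h: np.ndarray
    r: np.ndarray
    t: float = 0.0


@dataclass
class SteadyState:
    """Converged fixed point for a static stimulus condition."""

    h: np.ndarray
    r: np.ndarray
    residual: float
    energy: float
    condition: StimulusEnsemble
    converged: bool
    iterations: int
    solver: str

    @property
    def state(self) -> NetworkState:
        return NetworkState(h=self.h, r=self.r, t=np.inf)


@dataclass
class Trajectory:
    """Euler trajectory sampled on a regular grid."""

    times: np.ndarray
    H: np.ndarray  # (n_times, N) voltages

    @property
    def n_times(self) -> int:
        return self.times.shape[0]

    def rates(self, theta: float = 0.0) -> np.ndarray:
        return np.maximum(self.H - theta, 0.0)

    def state_at(self, t: float, theta: float = 0.0) -> NetworkState:
        i = int(np.argmin(np.abs(self.times - t)))
        h = self.H[i]
        return NetworkState(h=h, r=np.maximum(h - theta, 0.0), t=float(self.times[i]))


def _residual(net: RecurrentNetwork, h: np.ndarray, IF: np.ndarray) -> float:
    rhs = -h + net.params.b * (net.recurrent_drive(net.phi(h)) + IF)
    return float(np.max(np.abs(rhs)))


def _solve_active_lowrank(net, IF, active, cg: bool):
    """Exact solve of the linear fixed point on a trial active set."""
    b, theta, N = net.params.b, net.params.theta, net.N
    U = net.weights.stacked()
    UA = U[active]
    cA = b * IF[active] + (b / N) * (UA @ (UA.sum(axis=0) * theta))
    if not cg:
        # Woodbury: (I + (b/N) UA UA^T)^{-1} c = c - UA ((N/b)I + G)^{-1} UA^T c
        G = UA.T @ UA
        G[np.diag_indices_from(G)] += N / b
        cf = scipy.linalg.cho_factor(G, check_finite=False)
        hA = cA - UA @ scipy.linalg.cho_solve(cf, UA.T @ cA, check_finite=False)
    else:
        nA = UA.shape[0]

        def mv(z):
            return z + (b / N) * (UA @ (UA.T @ z))

        op = scipy.sparse.linalg.LinearOperator((nA, nA), matvec=mv)
        hA, info = scipy.sparse.linalg.cg(op, cA, rtol=1e-13, atol=0.0, maxiter=10 * nA)
        if info != 0:
            raise ConvergenceError(f"inner CG did not converge (info={info})")
    return hA


def _solve_active_dense(net, IF, active):
    b, theta = net.params.b, net.params.theta
    JAA = net.J[np.ix_(active, active)]
    M = -b * JAA
    M[np.diag_indices_from(M)] += 1.0
    rhs = b * IF[active] - b * theta * JAA.sum(axis=1)
    return np.linalg.solve(M, rhs)


def _full_h_from_active(net, IF, active, hA):
    b, theta, N = net.params.b, net.params.theta, net.N
    r = np.zeros(net.N)
    r[active] = np.maximum(hA - theta, 0.0)
    h = b * (net.recurrent_drive(r) + IF)
    h[active] = hA
    return h, r


def steady_state(
    net: RecurrentNetwork,
    stim: StimulusEnsemble | None = None,
    h0: np.ndarray | None = None,
    max_outer: int = 200,
    IF: np.ndarray | None = None,
) -> SteadyState:
    """Solve the static-stimulus fixed point to the network's tolerance.

    For the prescribed (negative-semidefinite, symmetric) connectivity the
    energy is strictly convex, so the returned fixed point is independent of
    the initialization ``h0``.
    """
    if IF is None:
        if stim is None:
            raise ParameterError("provide either a stimulus condition or a raw input IF")
        IF = net.feedforward(stim)
    else:
        IF = np.asarray(IF, dtype=float)

    def _E(r):
        return energy(net, r, stim) if stim is not None else float("nan")

    b, theta, tol = net.params.b, net.params.theta, net.params.tol
    h = b * IF.copy() if h0 is None else np.asarray(h0, dtype=float).copy()
    lowrank = not (net.pruned or net.params.exclude_diagonal)
    use_cg = 2 * net.P > 600
    gamma = 1.0 / (1.0 + b * net.gram_norm())
    scale = max(1.0, float(np.max(np.abs(b * IF))) if IF.size else 1.0)
    # the residual tolerance is relative to the drive scale once that exceeds 1
    tol = tol * scale
    history = []
    total_newton = 0
    n_warm = 50
    while total_newton < max_outer:
        # Damped Picard warmup: brings h close enough that the active set of
        # the exact solution is (nearly) identified before Newton steps.
        for _ in range(n_warm):
            target = b * (net.recurrent_drive(net.phi(h)) + IF)
            res = float(np.max(np.abs(target - h)))
            if res <= tol or res < 1e-6 * scale:
                break
            h = h + gamma * (target - h)
        # Active-set Newton: exact solve on the current trial set.
        seen: set[bytes] = set()
        cycled = False
        for _ in range(30):
            total_newton += 1
            active = h > theta
            key = np.packbits(active).tobytes()
            if key in seen:
                cycled = True
                break
            seen.add(key)
            if not np.any(active):
                h = b * IF
                res = _residual(net, h, IF)
                history.append(res)
                if res <= tol:
                    r = net.phi(h)
                    return SteadyState(h, r, res, _E(r), stim, True,
                                       total_newton, "active_set")
                continue
            try:
                hA = (
                    _solve_active_lowrank(net, IF, active, cg=use_cg)
                    if lowrank
                    else _solve_active_dense(net, IF, active)
                )
            except (np.linalg.LinAlgError, ConvergenceError):
                cycled = True
                break
            h, r = _full_h_from_active(net, IF, active, hA)
            res = _residual(net, h, IF)
            history.append(res)
            if res <= tol and np.array_equal(h > theta, active):
                return SteadyState(h, r, res, _E(r), stim, True,
                                   total_newton, "active_set")
        if cycled:
            n_warm = min(4 * n_warm, 20_000)
        else:
            break

    # Fallback 1: convex energy minimization, then one exact polish solve.
    if lowrank and stim is not None:
        r0 = net.phi(h)

        def fun(r):
            return energy(net, r, stim), energy_gradient(net, r, stim)

        opt = scipy.optimize.minimize(
            fun, r0, jac=True, method="L-BFGS-B",
            bounds=[(0.0, None)] * net.N,
            options={"maxiter": 500, "ftol": 1e-16, "gtol": 1e-12},
        )
        h_opt = b * (net.recurrent_drive(opt.x) + IF)
        active = h_opt > theta
        try:
            hA = _solve_active_lowrank(net, IF, active, cg=use_cg)
            h, r = _full_h_from_active(net, IF, active, hA)
            res = _residual(net, h, IF)
            history.append(res)
            if res <= tol:
                return SteadyState(h, r, res, _E(r), stim, True, -1, "energy+polish")
        except (np.linalg.LinAlgError, ConvergenceError):
            h = h_opt

    # Fallback 2: damped Picard iteration with a spectrally safe step.
    gamma = 1.0 / (1.0 + b * net.gram_norm())
    res = np.inf
    for it in range(net.params.max_iter):
        target = b * (net.recurrent_drive(net.phi(h)) + IF)
        res = float(np.max(np.abs(target - h)))
        if res <= tol:
            r = net.phi(h)
            return SteadyState(h, r, res, _E(r), stim, True, it, "damped")
        h = h + gamma * (target - h)
    history.append(res)
    raise ConvergenceError(
        f"steady state did not converge to tol={tol:g} (residual {res:.3e})",
        residuals=history,
    )


def stable_dt(net: RecurrentNetwork) -> float:
    """Explicit-Euler stability bound dt < 1 / (1 + b * lambda_max(-J))."""
    return 1.0 / (1.0 + net.params.b * net.gram_norm())


def simulate(
    net: RecurrentNetwork,
    stim,
    T: float,
    dt: float | None = None,
    h0: np.ndarray | None = None,
    record_dt: float | None = None,
) -> Trajectory:
    """Integrate the dynamics with explicit Euler.

    Parameters
    ----------
    stim : StimulusEnsemble or callable t -> StimulusEnsemble
        Static condition, or a time course for transient protocols.
    dt : float, optional
        Step size; defaults to the network's ``params.dt`` capped at 90% of the
        explicit-Euler stability bound.  An explicitly requested unstable step
        raises ``IntegrationError``.
    record_dt : float, optional
        Sampling interval of the returned trajectory (defaults to ``dt``).
    """
    dt_max = stable_dt(net)
    if dt is None:
        dt = min(net.params.dt, 0.9 * dt_max)
    elif dt >= dt_max:
        raise IntegrationError(
            f"dt={dt:g} unstable for gain b={net.params.b:g} "
            f"(explicit Euler requires dt < {dt_max:g})"
        )
    if T <= 0:
        raise ParameterError("T must be positive")
    static = isinstance(stim, StimulusEnsemble)
    IF = net.feedforward(stim) if static else None
    n_steps = int(np.ceil(T / dt))
    every = max(1, int(round((record_dt or dt) / dt)))
    h = np.zeros(net.N) if h0 is None else np.asarray(h0, dtype=float).copy()
    times = [0.0]
    H = [h.copy()]
    cap = 1e9
    b = net.params.b
    for k in range(1, n_steps + 1):
        t = k * dt
        I = IF if static else net.feedforward(stim(t - dt))
        h = h + dt * (-h + b * (net.recurrent_drive(net.phi(h)) + I))
        if not np.all(np.isfinite(h)) or np.max(np.abs(h)) > cap:
            raise IntegrationError(
                f"trajectory diverged at t={t:.3f} with dt={dt:g}, b={b:g}"
            )
        if k % every == 0 or k == n_steps:
            times.append(t)
            H.append(h.copy())
    return Trajectory(times=np.asarray(times), H=np.asarray(H))
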