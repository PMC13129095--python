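"""Balance levels, the closed-form variance ratio, gain calibration, geometry.

The *balance level* of neuron i at steady state is

    B_i = | I^F_i / (I^F_i - I^R_i) |,

the ratio of the feedforward input to the net input, where I^R_i = -(J r)_i is
the recurrent (prediction-carrying) component.  Since h_i = b (I^F_i - I^R_i)
at steady state, B_i = |b I^F_i / h_i|.  Large B means tight balance (the
recurrent prediction nearly cancels the stimulus input); B near 0 means the
net input is dominated by unpredicted drive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .dynamics import SteadyState, steady_state
from .errors import (
    ConvergenceError,
    NonIdentifiableError,
    ParameterError,
    RangeError,
)
from .network import RecurrentNetwork, make_network
from .stimuli import StimulusEnsemble, condition, pair_conditions
from .weights import MU_TRAINED

#: median optimal balance level fitted to intracellular visual-cortex voltages
#: in the overtrained (single-pair, alpha ~ 0) regime
B_STAR_DATA = 162.0


@dataclass
class BalanceProfile:
    """Per-neuron balance levels in one stimulus condition."""

    B: np.ndarray
    flagged: np.ndarray  # |net input| below floor: B unreliable, not dropped
    condition: str

    @property
    def median(self) -> float:
        return float(np.median(self.B[~self.flagged]))

    @property
    def iqr(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.B[~self.flagged], [25, 75])
        return float(lo), float(hi)


@dataclass
class GeometrySummary:
    """Population-geometry statistics of one stimulus-pair's responses."""

    cos_xy: float          # cos(r_x, r_y): mismatch responses to the two stimuli
    cos_match_x: float     # cos(r_xy, r_x): match vs x-only mismatch
    cos_match_y: float     # cos(r_xy, r_y)
    rate_ratio: float      # mean mismatch rate / mean match rate
    mean_subtracted: bool


def balance_levels(
    net: RecurrentNetwork,
    stim: StimulusEnsemble,
    ss: SteadyState | None = None,
    floor: float = 1e-8,
) -> BalanceProfile:
    """Steady-state balance levels B_i for one static condition."""
    if ss is None:
        ss = steady_state(net, stim)
    elif ss.residual > net.params.tol * 10 * max(
        1.0, net.params.b * float(np.max(np.abs(net.feedforward(stim))))
    ):
        raise ConvergenceError(
            f"refusing to compute balance from an unconverged steady state "
            f"(residual {ss.residual:.3e})"
        )
    IF = net.feedforward(stim)
    net_input = ss.h / net.params.b  # = I^F + (J r) = I^F - I^R
    flagged = np.abs(net_input) < floor
    denom = np.where(flagged, np.nan, net_input)
    with np.errstate(divide="ignore", invalid="ignore"):
        B = np.abs(IF / denom)
    B = np.where(flagged, np.inf, B)
    return BalanceProfile(B=B, flagged=flagged, condition=stim.label)


def time_dependent_balance(h: np.ndarray, IF: np.ndarray, b: float, floor: float = 1e-8):
    """B_i(t) = |b I^F_i(t) / h_i(t)|, masked where |h| is below the floor.

    At steady state this coincides with the static definition.  Returns
    (B, valid_mask) with B = nan where masked.
    """
    valid = np.abs(h) > floor
    with np.errstate(divide="ignore", invalid="ignore"):
        B = np.abs(b * IF / h)
    return np.where(valid, B, np.nan), valid


def variance_ratio(b: float, mu: float) -> float:
    """Closed-form sigma^2_mismatch / sigma^2_match of the voltages (P=1, theta=0).

    Evaluates the large-N expression

        (1/2) [mu^2 + (1-mu^2)(1+b/2)^2]
              / [mu^2 + mu + (1-mu^2)(1 + b + (1-mu) b^2/4)].

    Limits: 1/2 at mu=0 (any b), 1/4 at mu=1 (any b).
    """
    if b <= 0:
        raise ParameterError(f"b must be positive, got {b}")
    if not 0 <= mu <= 1:
        raise ParameterError(f"mu must be in [0, 1], got {mu}")
    num = mu**2 + (1 - mu**2) * (1 + b / 2) ** 2
    den = mu**2 + mu + (1 - mu**2) * (1 + b + (1 - mu) * b**2 / 4)
    return 0.5 * num / den


def variance_ratio_range(mu: float) -> tuple[float, float]:
    """Attainable (b -> 0+, b -> inf) limits of the variance ratio at fixed mu."""
    lo = 0.5 / (1 + mu)
    hi = 0.5 / (1 - mu) if mu < 1 else 0.25
    return lo, hi


def invert_variance_ratio(ratio: float, mu: float, b_max: float = 1e6) -> float:
    """Solve variance_ratio(b, mu) = ratio for the gain b (bracketed root).

    Raises ``NonIdentifiableError`` at mu = 0 (the ratio is 1/2 for every b)
    and ``RangeError`` when the requested ratio is not attainable.
    """
    if not 0 <= mu <= 1:
        raise ParameterError(f"mu must be in [0, 1], got {mu}")
    if mu == 0:
        raise NonIdentifiableError(
            "at mu=0 the variance ratio equals 1/2 for every gain; b is not identifiable"
        )
    lo, hi = variance_ratio_range(mu)
    lo_v = variance_ratio(1e-12, mu)
    hi_v = variance_ratio(b_max, mu)
    lo_att, hi_att = min(lo_v, hi_v), max(lo_v, hi_v)
    if not lo_att <= ratio <= hi_att:
        raise RangeError(
            f"ratio {ratio:.4g} outside the attainable range "
            f"({lo:.4g}, {hi:.4g}) for mu={mu}"
        )
    f = lambda b: variance_ratio(b, mu) - ratio
    b = scipy.optimize.brentq(f, 1e-12, b_max, xtol=1e-12, rtol=1e-12)
    return float(b)


def _median_balance(net: RecurrentNetwork, pair: int = 0, which: str = "match") -> float:
    stim = condition(net.P, which, pair=pair)
    return balance_levels(net, stim).median


def calibrate_gain_to_balance(
    target: float = B_STAR_DATA,
    mu: float = MU_TRAINED,
    N: int = 2000,
    P: int = 1,
    seed: int = 0,
    theta: float = 0.0,
    b_bracket: tuple[float, float] = (0.5, 2000.0),
) -> float:
    """Find the gain b at which the median match-condition balance equals ``target``.

    At P=1 the match-condition balance is homogeneous across neurons
    (h is exactly proportional to w+v), so the median is sharp; the map
    b -> median B is monotone increasing and is inverted by a bracketed root
    search on an actual sampled network.
    """
    def f(b):
        net = make_network(N=N, P=P, mu=mu, b=b, seed=seed, theta=theta)
        return _median_balance(net) - target

    return float(scipy.optimize.brentq(f, *b_bracket, xtol=1e-3, rtol=1e-6))


@dataclass
class OptimalGainResult:
    b_star: float
    balance_median: float
    balance_iqr: tuple[float, float]
    mismatch_rate: float
    match_rate: float
    scanned_b: np.ndarray
    scanned_mismatch_rate: np.ndarray


def optimal_gain(
    net_factory,
    mismatch_rate_floor: float,
    b_grid: np.ndarray | None = None,
    refine_rel: float = 1e-3,
    balance_condition: str = "match",
    pair: int = 0,
) -> OptimalGainResult:
    """Smallest gain meeting the mismatch-rate floor (= minimal match rate).

    The average mismatch and match responses both increase with b, so the
    constrained problem "mean mismatch rate >= floor, minimize the (nonzero)
    mean match rate" is solved by the smallest admissible b: a monotone scan
    over a logarithmic grid followed by bisection refinement.

    Parameters
    ----------
    net_factory : callable b -> RecurrentNetwork
        Builds the network family over the gain (fixed weights/seed).
    """
    if b_grid is None:
        b_grid = np.logspace(np.log10(0.1), 3, 25)

    cache: dict[float, tuple[float, float]] = {}
    warm: dict[str, np.ndarray] = {}

    def rates(b):
        if b not in cache:
            net = net_factory(b)
            mism = steady_state(net, condition(net.P, "x_only", pair=pair),
                                h0=warm.get("x_only"))
            match = steady_state(net, condition(net.P, "match", pair=pair),
                                 h0=warm.get("match"))
            warm["x_only"], warm["match"] = mism.h, match.h
            cache[b] = (float(mism.r.mean()), float(match.r.mean()))
        return cache[b]

    mism_rates = np.array([rates(b)[0] for b in b_grid])
    if np.any(np.diff(mism_rates) < -1e-9 * np.maximum(mism_rates[:-1], 1e-12)):
        raise ConvergenceError("mismatch mean rate is not monotone on the scanned grid")
    feasible = mism_rates >= mismatch_rate_floor
    if not np.any(feasible):
        raise ParameterError(
            f"mismatch-rate floor {mismatch_rate_floor:g} infeasible on grid "
            f"b in [{b_grid[0]:g}, {b_grid[-1]:g}] (max rate {mism_rates.max():g})"
        )
    i = int(np.argmax(feasible))
    if i == 0:
        b_lo, b_hi = b_grid[0] * 1e-3, b_grid[0]
    else:
        b_lo, b_hi = b_grid[i - 1], b_grid[i]
    while (b_hi - b_lo) / b_hi > refine_rel:
        b_mid = np.sqrt(b_lo * b_hi)
        if rates(b_mid)[0] >= mismatch_rate_floor:
            b_hi = b_mid
        else:
            b_lo = b_mid
    b_star = float(b_hi)
    net = net_factory(b_star)
    prof = balance_levels(net, condition(net.P, balance_condition, pair=pair))
    mr, mtr = rates(b_star)
    return OptimalGainResult(
        b_star=b_star,
        balance_median=prof.median,
        balance_iqr=prof.iqr,
        mismatch_rate=mr,
        match_rate=mtr,
        scanned_b=np.asarray(b_grid),
        scanned_mismatch_rate=mism_rates,
    )


def _cos(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ParameterError("zero-norm response vector; cosine undefined")
    return float(np.dot(a, b) / (na * nb))


def geometry_summary(
    r_x: np.ndarray,
    r_y: np.ndarray,
    r_xy: np.ndarray,
    mean_subtract: bool = True,
) -> GeometrySummary:
    """Angles between condition-response vectors and the mismatch/match ratio."""
    match_mean = float(r_xy.mean())
    mism_mean = float((r_x.mean() + r_y.mean()) / 2)
    if mean_subtract:
        r_x = r_x - r_x.mean()
        r_y = r_y - r_y.mean()
        r_xy = r_xy - r_xy.mean()
    return GeometrySummary(
        cos_xy=_cos(r_x, r_y),
        cos_match_x=_cos(r_xy, r_x),
        cos_match_y=_cos(r_xy, r_y),
        rate_ratio=mism_mean / match_mean if match_mean > 0 else np.inf,
        mean_subtracted=mean_subtract,
    )


def pair_geometry(net: RecurrentNetwork, pair: int = 0, mean_subtract: bool = True) -> GeometrySummary:
    """Geometry summary of one pair's canonical conditions at steady state."""
    conds = pair_conditions(net.P, pair)
    ss = {lab: steady_state(net, st) for lab, st in conds.items()}
    return geometry_summary(
        ss["x_only"].r, ss["y_only"].r, ss["match"].r, mean_subtract=mean_subtract
    )
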