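"""Functional cell-type classification and desegregation analyses.

For one stimulus-pair, with steady-state voltages h^x (x-only mismatch),
h^xy (match) and a classification scale sigma (the standard deviation of the
x-only voltage distribution after learning, mu = 0.97):

* representation (R) neuron:    h^x > sigma/2  and  |h^x - h^xy| < sigma/2
* prediction-error (PE) neuron: h^x > sigma/2  and   h^x - h^xy  > sigma/2

Delta = h^x - h^xy is the mismatch-minus-match response.  The two criteria
are mutually exclusive for the same pair.  In the high-dimensional regime
(alpha > 0) and for inhibitory populations the voltages are centered before
applying the criteria.  A *mixed-representation* neuron is responsive to two
pairs and classified R for one but PE for the other; a *dedicated PE* neuron
is PE for at least one pair and never R for any pair it responds to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .dynamics import steady_state
from .errors import InsufficientDataError, ParameterError
from .network import RecurrentNetwork, make_network
from .stimuli import condition
from .weights import MU_TRAINED

LABELS = ("R", "PE", "none")


@dataclass
class CellTypeTable:
    """Per-(neuron, pair) labels and Delta values."""

    table: pd.DataFrame  # columns: pair, neuron, h_x, h_xy, delta, responsive, label
    sigma: float
    centered: bool

    def labels(self, pair: int) -> np.ndarray:
        sub = self.table[self.table["pair"] == pair].sort_values("neuron")
        return sub["label"].to_numpy()

    def fraction(self, label: str, pair: int | None = None) -> float:
        t = self.table if pair is None else self.table[self.table["pair"] == pair]
        return float((t["label"] == label).mean())


@dataclass
class SegregationResult:
    segregation_index: float
    representation_similarity: float | None
    n_neurons: int
    index_se: float


def classify_pair(
    h_x: np.ndarray,
    h_xy: np.ndarray,
    sigma: float,
    center: bool = False,
) -> pd.DataFrame:
    """Label every neuron for one stimulus-pair from its two condition voltages."""
    if sigma <= 0:
        raise ParameterError(f"classification scale sigma must be > 0, got {sigma}")
    hx = h_x - h_x.mean() if center else np.asarray(h_x, dtype=float)
    hxy = h_xy - h_xy.mean() if center else np.asarray(h_xy, dtype=float)
    delta = hx - hxy
    responsive = hx > sigma / 2
    is_r = responsive & (np.abs(delta) < sigma / 2)
    is_pe = responsive & (delta > sigma / 2)
    label = np.where(is_r, "R", np.where(is_pe, "PE", "none"))
    return pd.DataFrame(
        {
            "neuron": np.arange(hx.shape[0]),
            "h_x": hx,
            "h_xy": hxy,
            "delta": delta,
            "responsive": responsive,
            "label": label,
        }
    )


def pair_voltages(net: RecurrentNetwork, pair: int, stimulus: str = "x"):
    """Steady-state (h_mismatch, h_match) voltages of one pair.

    ``stimulus='x'`` uses the x-only mismatch; ``'y'`` the y-only one.
    """
    mism = "x_only" if stimulus == "x" else "y_only"
    h_m = steady_state(net, condition(net.P, mism, pair=pair)).h
    h_xy = steady_state(net, condition(net.P, "match", pair=pair)).h
    return h_m, h_xy


def classification_sigma(
    N: int,
    P: int,
    b: float,
    seed: int,
    theta: float = 0.0,
    pair: int = 0,
    center: bool = False,
) -> float:
    """The classification scale: std of the x-only voltages after learning.

    Evaluated on a network with the same size, gain and seed but mu = 0.97,
    and then reused across learning stages of that network family.
    """
    ref = make_network(N=N, P=P, mu=MU_TRAINED, b=b, seed=seed, theta=theta)
    h_x, _ = pair_voltages(ref, pair)
    if center:
        h_x = h_x - h_x.mean()
    return float(np.std(h_x))


def classify(
    net: RecurrentNetwork,
    pairs=None,
    sigma: float | None = None,
    center: bool | None = None,
    stimulus: str = "x",
) -> CellTypeTable:
    """Classify every neuron for the requested pairs of a network."""
    if pairs is None:
        pairs = range(net.P)
    if center is None:
        center = net.alpha > 0.01  # voltages are centered only at alpha ~ 0
    if sigma is None:
        sigma = classification_sigma(
            net.N, net.P, net.params.b, net.weights.seed, net.params.theta, center=center
        )
    frames = []
    for k in pairs:
        h_m, h_xy = pair_voltages(net, k, stimulus=stimulus)
        df = classify_pair(h_m, h_xy, sigma, center=center)
        df.insert(0, "pair", k)
        frames.append(df)
    return CellTypeTable(table=pd.concat(frames, ignore_index=True), sigma=sigma, centered=center)


def negative_pe_mask(h_y: np.ndarray, h_xy: np.ndarray, sigma: float, center: bool = False):
    """Mirrored criterion: active when x is expected (y present) but absent.

    In the binary one-to-one pairing design this coincides with the positive
    PE criterion applied to the y stimulus; it is reported separately and is
    excluded from the headline PE fraction.
    """
    hy = h_y - h_y.mean() if center else h_y
    hxy = h_xy - h_xy.mean() if center else h_xy
    return (hy > sigma / 2) & (hy - hxy > sigma / 2)


def pe_r_fractions(
    N: int,
    b: float,
    mus,
    n_instances: int = 10,
    seed: int = 0,
    theta: float = 0.0,
    P: int = 1,
) -> pd.DataFrame:
    """R and PE fractions vs learning stage, with Monte-Carlo SD over networks."""
    rows = []
    for inst in range(n_instances):
        s = seed + 1000 * inst
        sigma = classification_sigma(N, P, b, s, theta)
        for mu in mus:
            net = make_network(N=N, P=P, mu=mu, b=b, seed=s, theta=theta)
            df = classify_pair(*pair_voltages(net, 0), sigma)
            rows.append(
                {
                    "instance": inst,
                    "mu": mu,
                    "frac_R": float((df["label"] == "R").mean()),
                    "frac_PE": float((df["label"] == "PE").mean()),
                }
            )
    raw = pd.DataFrame(rows)
    out = raw.groupby("mu").agg(
        frac_R=("frac_R", "mean"),
        frac_R_sd=("frac_R", "std"),
        frac_PE=("frac_PE", "mean"),
        frac_PE_sd=("frac_PE", "std"),
    )
    return out.reset_index()


@dataclass
class MixedResult:
    fraction: float
    n_dually_responsive: int
    joint: pd.DataFrame  # per dually-responsive neuron: delta_1, delta_2, label_1, label_2


def mixed_fraction(
    net: RecurrentNetwork,
    pairs: tuple[int, int] = (0, 1),
    sigma: float | None = None,
    center: bool | None = None,
) -> MixedResult:
    """Fraction of dually-responsive neurons with differing R/PE types."""
    if net.P < 2:
        raise ParameterError("mixed_fraction needs a network with P >= 2")
    tab = classify(net, pairs=pairs, sigma=sigma, center=center)
    a = tab.table[tab.table["pair"] == pairs[0]].set_index("neuron")
    c = tab.table[tab.table["pair"] == pairs[1]].set_index("neuron")
    dually = a["responsive"] & c["responsive"]
    n = int(dually.sum())
    if n == 0:
        raise InsufficientDataError("no neurons responsive to both stimulus-pairs")
    la, lc = a.loc[dually, "label"], c.loc[dually, "label"]
    mixed = ((la == "R") & (lc == "PE")) | ((la == "PE") & (lc == "R"))
    joint = pd.DataFrame(
        {
            "delta_1": a.loc[dually, "delta"],
            "delta_2": c.loc[dually, "delta"],
            "label_1": la,
            "label_2": lc,
            "mixed": mixed,
        }
    )
    return MixedResult(fraction=float(mixed.mean()), n_dually_responsive=n, joint=joint)


def dedicated_pe_fraction(
    net: RecurrentNetwork,
    pairs=None,
    sigma: float | None = None,
    center: bool | None = None,
) -> float:
    """Fraction of neurons that are PE for >= 1 pair and never R where responsive.

    With many pairs the evaluation may be restricted to a subset via ``pairs``
    (the fraction is then an estimate over that subset).
    """
    if net.P < 2:
        raise ParameterError("dedicated_pe_fraction needs P >= 2")
    tab = classify(net, pairs=pairs, sigma=sigma, center=center)
    t = tab.table
    by = t.pivot(index="neuron", columns="pair", values="label")
    any_pe = (by == "PE").any(axis=1)
    any_r = (by == "R").any(axis=1)
    return float((any_pe & ~any_r).mean())


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        raise ParameterError("zero-variance vector; Pearson correlation undefined")
    return float(scipy.stats.pearsonr(a, b).statistic)


def representation_similarity(resp_a: np.ndarray, resp_b: np.ndarray) -> float:
    """Pearson correlation of passive population response-change vectors."""
    return pearson(np.asarray(resp_a, float), np.asarray(resp_b, float))


def segregation_index(
    recording,
    expected_id: str = "expected",
    probe_id: str = "probe",
    n_boot: int = 100,
    seed: int = 0,
) -> SegregationResult:
    """Pearson correlation of per-neuron Delta values for two stimuli.

    Delta = mismatch (passive) minus match (active) response change.  Only
    neurons responsive in the passive condition to *both* stimuli enter; the
    responsiveness threshold is mean + 0.5 SD of the passive response to the
    expected stimulus.  The standard error is obtained by resampling neurons.
    """
    passive_exp = recording.response_change(expected_id, "passive")
    passive_probe = recording.response_change(probe_id, "passive")
    thresh = passive_exp.mean() + 0.5 * passive_exp.std()
    responsive = (passive_exp > thresh) & (passive_probe > thresh)
    n = int(responsive.sum())
    if n < 3:
        raise InsufficientDataError(
            f"only {n} neurons responsive to both stimuli; need >= 3"
        )
    d_exp = passive_exp - recording.response_change(expected_id, "active")
    d_probe = passive_probe - recording.response_change(probe_id, "active")
    d_exp, d_probe = d_exp[responsive], d_probe[responsive]
    index = pearson(d_exp, d_probe)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if np.std(d_exp[idx]) == 0 or np.std(d_probe[idx]) == 0:
            continue
        boots.append(pearson(d_exp[idx], d_probe[idx]))
    try:
        sim = representation_similarity(passive_exp[responsive], passive_probe[responsive])
    except ParameterError:
        sim = None
    return SegregationResult(
        segregation_index=index,
        representation_similarity=sim,
        n_neurons=n,
        index_se=float(np.std(boots)) if boots else np.nan,
    )
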