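"""Match/mismatch decoders on stimulus inputs vs network responses.

The condition "is the presented x stimulus accompanied by its associated y?"
is not linearly separable from the raw (x, y) input vectors once several
pairs are interleaved, but becomes linearly separable from the network's
nonlinearly transformed steady-state responses after learning.  After
learning, even a one-dimensional readout -- the population mean firing rate
with an optimized threshold -- performs almost as well as the max-margin
(linear SVM) decoder, because match responses are globally suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.svm import LinearSVC

from .dynamics import steady_state
from .errors import ParameterError
from .network import RecurrentNetwork
from .stimuli import StimulusEnsemble, condition

DECODER_KINDS = ("max_margin", "mean_rate_threshold")


@dataclass
class DecodeDataset:
    """Balanced samples of match (label 1) and mismatch (label 0) trials."""

    X: np.ndarray          # (n_samples, n_features)
    labels: np.ndarray     # 1 = match, 0 = mismatch
    pair_ids: np.ndarray
    feature_space: str     # 'rates' or 'inputs'
    noise_sd: float
    degenerate: bool       # True when noise_sd == 0 (duplicate rows per condition)


def build_decode_dataset(
    net: RecurrentNetwork,
    pairs=None,
    noise_sd: float = 2.0,
    n_samples: int = 200,
    seed: int = 0,
    feature_space: str = "rates",
    mismatch_kinds: tuple = ("x_only", "y_only"),
    noise_model: str = "input",
) -> DecodeDataset:
    """Per-trial feature vectors for the match/mismatch decoding task.

    Mismatch trials alternate over ``mismatch_kinds``: single-component
    presentations (``x_only``/``y_only``), or ``cross_pair`` controls in which
    an x component appears with the y component of a *different* pair.  The
    cross-pair design equates the number of active stimulus components across
    classes, so no linear readout of the raw inputs can separate them (a
    generalized XOR), which is the appropriate control when decoding from the
    stimulus space.  Features are steady-state rates (``'rates'``) or the raw
    stimulus vectors (``'inputs'``); ``n_samples`` counts trials per class.

    ``noise_model='input'`` (default) adds Gaussian noise of sd ``noise_sd``
    to the stimulus amplitude vectors and recomputes the steady state per
    trial, so rate features carry the network's nonlinear transform of the
    corrupted stimulus; ``'feature'`` adds the noise to the feature vectors
    directly.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if n_samples < 2:
        raise ParameterError("need at least 2 samples per class")
    if feature_space not in ("rates", "inputs"):
        raise ParameterError(f"unknown feature space {feature_space!r}")
    if pairs is None:
        pairs = list(range(net.P))
    for kind in mismatch_kinds:
        if kind not in ("x_only", "y_only", "cross_pair"):
            raise ParameterError(f"unknown mismatch kind {kind!r}")
        if kind == "cross_pair" and net.P < 2:
            raise ParameterError("cross_pair mismatches need P >= 2")
    if noise_model not in ("input", "feature"):
        raise ParameterError(f"unknown noise model {noise_model!r}")
    rng = np.random.default_rng(seed)
    base = {}
    warm = {}

    def features(lab, k, partner=None):
        key = (k, lab, partner)
        if key not in base:
            stim = condition(net.P, lab, pair=k, cross_partner=partner)
            if noise_model == "input" and noise_sd > 0:
                xs = stim.x + noise_sd * rng.standard_normal(net.P)
                ys = stim.y + noise_sd * rng.standard_normal(net.P)
                noisy = StimulusEnsemble(xs, ys, label=stim.label)
                if feature_space == "rates":
                    ss = steady_state(net, noisy, h0=warm.get(key))
                    warm[key] = ss.h
                    return ss.r
                return np.concatenate([noisy.x, noisy.y])
            if feature_space == "rates":
                base[key] = steady_state(net, stim).r
            else:
                base[key] = np.concatenate([stim.x, stim.y])
        return base[key]

    X, y, pid = [], [], []
    for i in range(n_samples):
        k = pairs[i % len(pairs)]
        X.append(features("match", k))
        y.append(1)
        pid.append(k)
        kind = mismatch_kinds[i % len(mismatch_kinds)]
        if kind == "cross_pair":
            partner = pairs[(i // len(pairs) + 1 + i % len(pairs)) % len(pairs)]
            if partner == k:
                partner = pairs[(pairs.index(k) + 1) % len(pairs)]
            X.append(features("cross_pair", k, partner))
        else:
            X.append(features(kind, k))
        y.append(0)
        pid.append(k)
    X = np.asarray(X, dtype=float)
    if noise_model == "feature" and noise_sd > 0:
        X = X + noise_sd * rng.standard_normal(X.shape)
        if feature_space == "rates":
            X = np.maximum(X, 0.0)  # rates stay nonnegative
    return DecodeDataset(
        X=X,
        labels=np.asarray(y),
        pair_ids=np.asarray(pid),
        feature_space=feature_space,
        noise_sd=noise_sd,
        degenerate=noise_sd == 0,
    )


def _mean_rate_error(Xtr, ytr, Xte, yte) -> float:
    """1-d decoder: population-mean feature with the best training threshold."""
    mtr, mte = Xtr.mean(axis=1), Xte.mean(axis=1)
    order = np.argsort(mtr)
    m_sorted, y_sorted = mtr[order], ytr[order]
    cuts = np.concatenate([[m_sorted[0] - 1], (m_sorted[1:] + m_sorted[:-1]) / 2, [m_sorted[-1] + 1]])
    best_err, best_cut, best_sign = np.inf, cuts[0], 1
    for cut in cuts:
        for sign in (1, -1):
            pred = (sign * (m_sorted - cut) > 0).astype(int)
            err = float(np.mean(pred != y_sorted))
            if err < best_err:
                best_err, best_cut, best_sign = err, cut, sign
    pred_te = (best_sign * (mte - best_cut) > 0).astype(int)
    return float(np.mean(pred_te != yte))


def _svm_error(Xtr, ytr, Xte, yte, seed) -> float:
    grid = GridSearchCV(
        LinearSVC(dual="auto"),
        {"C": [0.01, 0.1, 1.0, 10.0]},
        cv=5,
        n_jobs=1,
    )
    grid.fit(Xtr, ytr)
    return float(np.mean(grid.predict(Xte) != yte))


def linear_decoder_error(
    dataset: DecodeDataset,
    decoder_kind: str = "max_margin",
    seed: int = 0,
    n_repeats: int = 10,
    test_size: float = 0.5,
) -> tuple[float, float]:
    """Held-out error (mean, SD over repeated 50/50 splits)."""
    if decoder_kind not in DECODER_KINDS:
        raise ParameterError(f"decoder_kind must be one of {DECODER_KINDS}")
    errs = []
    for rep in range(n_repeats):
        Xtr, Xte, ytr, yte = train_test_split(
            dataset.X, dataset.labels, test_size=test_size,
            random_state=seed + rep, stratify=dataset.labels,
        )
        if len(np.unique(ytr)) < 2 or len(np.unique(yte)) < 2:
            raise ParameterError("degenerate single-class split")
        if decoder_kind == "max_margin":
            errs.append(_svm_error(Xtr, ytr, Xte, yte, seed + rep))
        else:
            errs.append(_mean_rate_error(Xtr, ytr, Xte, yte))
    return float(np.mean(errs)), float(np.std(errs))


def cross_pair_generalization(
    net: RecurrentNetwork,
    noise_sd: float = 2.0,
    n_samples: int = 200,
    seed: int = 0,
) -> dict:
    """Train on the first half of the pairs, test on the held-out half.

    After learning the match/mismatch distinction is carried by a
    stimulus-independent signal (global suppression of predicted stimuli), so
    the population-mean-rate decoder transfers across stimulus-pairs without
    re-training.  A max-margin decoder, by contrast, may latch onto
    pair-specific response directions; both transfer errors are returned, and
    the mean-rate decoder is the one expected to generalize.
    """
    if net.P < 2:
        raise ParameterError("cross-pair generalization needs P >= 2")
    half = net.P // 2
    train_pairs = list(range(half))
    test_pairs = list(range(half, net.P))
    ds_train = build_decode_dataset(net, train_pairs, noise_sd, n_samples, seed)
    ds_test = build_decode_dataset(net, test_pairs, noise_sd, n_samples, seed + 1)
    Xtr, Xte, ytr, yte = train_test_split(
        ds_train.X, ds_train.labels, test_size=0.5, random_state=seed,
        stratify=ds_train.labels,
    )
    out = {
        "within_pair_error": _mean_rate_error(Xtr, ytr, Xte, yte),
        "cross_pair_error": _mean_rate_error(Xtr, ytr, ds_test.X, ds_test.labels),
        "within_pair_error_svm": _svm_error(Xtr, ytr, Xte, yte, seed),
    }
    grid = GridSearchCV(LinearSVC(dual="auto"), {"C": [0.01, 0.1, 1.0, 10.0]}, cv=5, n_jobs=1)
    grid.fit(Xtr, ytr)
    out["cross_pair_error_svm"] = float(np.mean(grid.predict(ds_test.X) != ds_test.labels))
    return out
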