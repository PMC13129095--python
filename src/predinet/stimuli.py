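"""Stimulus-pair ensembles.

A network learns ``P`` associations between two modalities.  The presence or
absence of the ``k``-th pair's components is encoded by the entries ``x[k]``
and ``y[k]`` of two length-``P`` amplitude vectors (1 = present, 0 = absent).
The canonical single-pair conditions are

* ``match``     -- ``x[k] = y[k] = 1`` (both components present),
* ``x_only``    -- ``x[k] = 1, y[k] = 0`` (mismatch; the x component alone),
* ``y_only``    -- ``x[k] = 0, y[k] = 1`` (mismatch; the y component alone),
* ``absent``    -- both zero,
* ``cross_pair``-- ``x[k] = 1`` together with ``y[k'] = 1`` of a *different*
  pair, a control in which the two presented components were never associated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError, ParameterError

CONDITION_LABELS = ("match", "x_only", "y_only", "absent", "cross_pair")


@dataclass(frozen=True)
class StimulusEnsemble:
    """Amplitudes of the two modalities for each of the P stimulus-pairs."""

    x: np.ndarray
    y: np.ndarray
    label: str = "custom"
    pair: int | None = None
    cross_partner: int | None = None

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
            raise DimensionError(
                f"x and y must be 1-d of equal length, got {x.shape} and {y.shape}"
            )
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def P(self) -> int:
        return self.x.shape[0]

    def is_absent(self) -> bool:
        return not (np.any(self.x) or np.any(self.y))


def condition(
    P: int,
    label: str,
    pair: int = 0,
    cross_partner: int | None = None,
    amplitude: float = 1.0,
) -> StimulusEnsemble:
    """Build the stimulus vectors for one canonical condition of one pair."""
    if label not in CONDITION_LABELS:
        raise ParameterError(f"unknown condition label {label!r}; one of {CONDITION_LABELS}")
    if not 0 <= pair < P:
        raise ParameterError(f"pair index {pair} outside [0, {P})")
    x = np.zeros(P)
    y = np.zeros(P)
    if label in ("match", "x_only", "cross_pair"):
        x[pair] = amplitude
    if label in ("match", "y_only"):
        y[pair] = amplitude
    if label == "cross_pair":
        if cross_partner is None or not 0 <= cross_partner < P or cross_partner == pair:
            raise ParameterError("cross_pair requires a distinct partner pair index")
        y[cross_partner] = amplitude
    return StimulusEnsemble(x, y, label=label, pair=pair, cross_partner=cross_partner)


def pair_conditions(P: int, pair: int = 0, amplitude: float = 1.0) -> dict[str, StimulusEnsemble]:
    """The three single-pair conditions used throughout the analyses."""
    return {
        lab: condition(P, lab, pair=pair, amplitude=amplitude)
        for lab in ("x_only", "y_only", "match")
    }
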