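"""YAML configuration parsing and validation for the command-line interface.

One YAML file drives a run.  Recognized sections:

model:
  N: 1000            # neurons
  P: 2               # stimulus-pairs
  mu: 0.97           # learning stage, scalar or list of length P
  b: 20.0            # gain
  theta: 0.0
  seed: 0
stimuli:
  pair: 0
  conditions: [x_only, y_only, match]
solver:
  tol: 1.0e-10
  dt: 0.01
output:
  dir: runs/latest

plus optional per-command blocks (``decode``, ``ei``, ``hier``, ``recording``,
``optimal_gain``, ``protocol``) documented in the README.  Unknown keys are
rejected with an error naming the offending field.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import ConfigError
from .stimuli import CONDITION_LABELS

_TOP_KEYS = {
    "model", "stimuli", "solver", "output",
    "decode", "ei", "hier", "recording", "optimal_gain", "protocol", "classify",
}
_MODEL_KEYS = {"N", "P", "mu", "b", "theta", "seed"}
_STIM_KEYS = {"pair", "conditions", "cross_partner", "amplitude"}
_SOLVER_KEYS = {"tol", "dt", "max_iter"}
_OUTPUT_KEYS = {"dir"}

DEFAULTS = {
    "model": {"N": 1000, "P": 2, "mu": 0.97, "b": 20.0, "theta": 0.0, "seed": 0},
    "stimuli": {"pair": 0, "conditions": ["x_only", "y_only", "match"], "amplitude": 1.0},
    "solver": {"tol": 1e-10, "dt": 0.01, "max_iter": 100_000},
    "output": {"dir": "runs/latest"},
}


def _check_keys(section: str, mapping: dict, allowed: set) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section}': {sorted(unknown)}")


def load_config(path) -> dict:
    """Parse and validate a YAML config, filling defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys("top level", raw, _TOP_KEYS)
    cfg = {k: dict(v) for k, v in DEFAULTS.items()}
    for section, allowed in (
        ("model", _MODEL_KEYS),
        ("stimuli", _STIM_KEYS),
        ("solver", _SOLVER_KEYS),
        ("output", _OUTPUT_KEYS),
    ):
        user = raw.get(section, {})
        if not isinstance(user, dict):
            raise ConfigError(f"section '{section}' must be a mapping")
        _check_keys(section, user, allowed)
        cfg[section].update(user)
    for extra in _TOP_KEYS - {"model", "stimuli", "solver", "output"}:
        if extra in raw:
            cfg[extra] = raw[extra]
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    m = cfg["model"]
    if not (isinstance(m["N"], int) and m["N"] >= 2):
        raise ConfigError(f"model.N must be an integer >= 2, got {m['N']}")
    if not (isinstance(m["P"], int) and m["P"] >= 1):
        raise ConfigError(f"model.P must be an integer >= 1, got {m['P']}")
    mus = m["mu"] if isinstance(m["mu"], (list, tuple)) else [m["mu"]]
    for mu in mus:
        if not 0 <= float(mu) <= 1:
            raise ConfigError(f"model.mu must lie in [0, 1], got {mu}")
    if not float(m["b"]) > 0:
        raise ConfigError(f"model.b must be positive, got {m['b']}")
    if float(m["theta"]) < 0:
        raise ConfigError(f"model.theta must be >= 0, got {m['theta']}")
    s = cfg["stimuli"]
    if not 0 <= int(s["pair"]) < m["P"]:
        raise ConfigError(f"stimuli.pair must be in [0, P), got {s['pair']}")
    for lab in s["conditions"]:
        if lab not in CONDITION_LABELS:
            raise ConfigError(
                f"stimuli.conditions entry {lab!r} not one of {CONDITION_LABELS}"
            )
    if not float(cfg["solver"]["tol"]) > 0:
        raise ConfigError("solver.tol must be positive")


def build_network_from_config(cfg: dict):
    from .network import make_network

    m, sv = cfg["model"], cfg["solver"]
    return make_network(
        N=m["N"], P=m["P"], mu=m["mu"], b=float(m["b"]), seed=int(m["seed"]),
        theta=float(m["theta"]), tol=float(sv["tol"]), dt=float(sv["dt"]),
        max_iter=int(sv["max_iter"]),
    )
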