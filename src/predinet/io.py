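"""CSV/JSON output helpers and the run manifest."""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(path, payload) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder) + "\n")
    return path


def steady_states_frame(states: dict) -> pd.DataFrame:
    """Long table (neuron_id, condition, time, h, r) from labelled steady states."""
    frames = []
    for label, ss in states.items():
        frames.append(
            pd.DataFrame(
                {
                    "neuron_id": np.arange(ss.h.shape[0]),
                    "condition": label,
                    "time": np.inf,
                    "h": ss.h,
                    "r": ss.r,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def trajectory_frame(traj, theta: float = 0.0, condition: str = "custom") -> pd.DataFrame:
    n_t, N = traj.H.shape
    t, n = np.meshgrid(traj.times, np.arange(N), indexing="ij")
    return pd.DataFrame(
        {
            "neuron_id": n.ravel(),
            "condition": condition,
            "time": t.ravel(),
            "h": traj.H.ravel(),
            "r": np.maximum(traj.H - theta, 0.0).ravel(),
        }
    )


def write_csv(path, frame: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


class RunManifest:
    """Records config, seeds and outputs of one CLI run (JSON sidecar)."""

    def __init__(self, command: str, config: dict, seed: int):
        self.payload = {
            "command": command,
            "package_version": __version__,
            "config": config,
            "seed": seed,
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": [],
        }

    def add_output(self, path) -> None:
        self.payload["outputs"].append(str(path))

    def write(self, out_dir) -> Path:
        self.payload["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        return write_json(Path(out_dir) / "manifest.json", self.payload)
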