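"""Output writers: trajectory CSV, matrix CSV, JSON reports, logging.

All floats are written with 17 significant digits so round-trips are
bit-exact and two runs of the same config produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from contextlib import contextmanager
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "write_trajectory",
    "write_matrix",
    "write_report",
    "trajectory_frame",
    "stage",
]

FLOAT_FMT = "%.17g"

log = logging.getLogger("permeq")


@contextmanager
def stage(name: str, **info):
    """Structured one-line-per-stage logging with wall time."""
    t0 = time.perf_counter()
    yield
    dt = time.perf_counter() - t0
    extras = " ".join(f"{k}={v}" for k, v in info.items())
    log.info("stage=%s wall=%.3fs %s", name, dt, extras)


def trajectory_frame(trajectory, state_labels: Optional[Sequence[str]] = None,
                     densities: Optional[np.ndarray] = None,
                     density_labels: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Trajectory as a DataFrame: time column, one column per state."""
    n = trajectory.states.shape[1]
    labels = list(state_labels) if state_labels else [f"x{i + 1}" for i in range(n)]
    data = {"time": trajectory.times}
    for k, lab in enumerate(labels):
        data[lab] = trajectory.states[:, k]
    if densities is not None:
        dlabels = list(density_labels) if density_labels else \
            [f"tau{k + 1}" for k in range(densities.shape[1])]
        for k, lab in enumerate(dlabels):
            data[lab] = densities[:, k]
    return pd.DataFrame(data)


def write_trajectory(trajectory, path, state_labels=None,
                     densities=None, density_labels=None) -> Path:
    """Write a trajectory CSV (17 significant digits)."""
    frame = trajectory_frame(trajectory, state_labels, densities, density_labels)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def write_matrix(M, path, state_labels: Optional[Sequence[str]] = None) -> Path:
    """Dump a matrix as CSV, row-major, with a header row of state labels."""
    M = M.toarray() if sp.issparse(M) else np.asarray(M)
    labels = list(state_labels) if state_labels else \
        [f"C{i + 1}" for i in range(M.shape[1])]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(M, columns=labels).to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return repr(obj)
    return obj


def write_report(report, path, config=None, seed: Optional[int] = None) -> Path:
    """Write a JSON report, embedding the config hash and seed when given."""
    payload = report.to_dict() if hasattr(report, "to_dict") else _jsonable(report)
    if config is not None:
        from .config import config_hash

        payload = {"config_hash": config_hash(config), **payload}
    if seed is not None:
        payload = {"seed": seed, **payload}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
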