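"""Tabular trajectory I/O and JSON run reports."""
from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .simulate import Trajectory

__all__ = ["write_trajectory", "read_trajectory", "run_report"]

TRAJECTORY_COLUMNS = ["t_hat", "p_hat", "r_hat", "alpha", "mu_hat", "log_vol"]


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as CSV with the canonical header."""
    traj.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_trajectory(path) -> Trajectory:
    """Read a trajectory CSV; validates the header, rejects ragged rows and
    non-increasing time grids."""
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file missing column {sorted(missing)[0]!r}")
    if df.isna().any().any():
        raise ValueError("trajectory file contains missing/ragged values")
    return Trajectory(
        times=df["t_hat"].to_numpy(),
        p_hat=df["p_hat"].to_numpy(),
        r_hat=df["r_hat"].to_numpy(),
        alphas=df["alpha"].to_numpy(),
        mu_hats=df["mu_hat"].to_numpy(),
        log_vol=df["log_vol"].to_numpy(),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_report(artifacts: dict, path, seed: int | None = None, solver: str | None = None) -> dict:
    """Write a JSON summary of computed artifacts with run metadata.

    ``artifacts`` maps names to JSON-serializable results (objective values,
    final ratios, arc labels, fit parameters, ...).
    """
    report = {
        "metadata": {
            "package": "selfreplicator",
            "version": _version,
            "seed": seed,
            "solver": solver,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
        "results": _jsonable(artifacts),
    }
    Path(path).write_text(json.dumps(report, indent=2))
    return report
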