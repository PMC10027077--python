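"""Reading and writing the package's plain-text interchange formats.

Trial tables are TSV with one row per trial; gaze traces are long-format
TSV keyed by trial index (columns ``trial_index, t_ms, x_deg, y_deg``);
ground truth and fit results are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelFit
from .synthetic_data import GazeTrace, GroundTruth

__all__ = [
    "write_trial_table",
    "read_trial_table",
    "write_traces",
    "read_traces",
    "write_ground_truth",
    "write_fit",
]


def write_trial_table(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_traces(traces: dict, path) -> None:
    """Write a ``{trial_index: GazeTrace}`` mapping as long-format TSV."""
    frames = [
        pd.DataFrame(
            {"trial_index": idx, "t_ms": tr.t_ms, "x_deg": tr.x_deg, "y_deg": tr.y_deg}
        )
        for idx, tr in sorted(traces.items())
    ]
    long = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["trial_index", "t_ms", "x_deg", "y_deg"]
    )
    long.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_traces(path) -> dict:
    long = pd.read_csv(path, sep="\t", na_values=["NA"])
    traces = {}
    for idx, sub in long.groupby("trial_index"):
        traces[int(idx)] = GazeTrace(
            t_ms=sub["t_ms"].to_numpy(float),
            x_deg=sub["x_deg"].to_numpy(float),
            y_deg=sub["y_deg"].to_numpy(float),
        )
    return traces


def write_ground_truth(ground_truth: GroundTruth, path, seed=None) -> None:
    Path(path).write_text(ground_truth.to_json(seed=seed))


def write_fit(fit: ModelFit, path, *, include_starts: bool = True) -> None:
    """Serialise a fit (parameters, objective, restart table) as JSON."""
    payload = {
        "params": dataclasses.asdict(fit.params),
        "effective_rate": fit.effective_rate,
        "rss": fit.rss,
        "n_fitted": fit.n_fitted,
        "k_params": fit.k_params,
        "bic": fit.bic,
        "n_starts": fit.n_starts,
        "converged": fit.converged,
        "degenerate": fit.degenerate,
        "predicted_hor_amp": np.asarray(fit.predicted.hor_amp).tolist(),
    }
    if include_starts:
        payload["starts"] = [dataclasses.asdict(rec) for rec in fit.starts]
    Path(path).write_text(json.dumps(payload, indent=2))
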