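"""Serialization of analysis artifacts.

Tidy tables go to CSV, matrices to MatrixMarket coordinate text with a JSON
sidecar (lag, state count, symmetrization flag, index map), structures to
multi-model PDB. Everything is plain text so artifacts diff and hash
cleanly in reproducibility manifests.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .errors import EstimationError
from .msm import CountMatrix, DiscreteTrajectorySet, MarkovModel

__all__ = [
    "save_count_matrix",
    "load_count_matrix",
    "save_model",
    "load_model",
    "save_dtraj",
    "load_dtraj",
]


def save_count_matrix(cm: CountMatrix, prefix) -> list[Path]:
    """Write counts as ``<prefix>.mtx`` + ``<prefix>.json``."""
    prefix = Path(prefix)
    mtx = prefix.with_suffix(".mtx")
    meta = prefix.with_suffix(".json")
    mmwrite(str(mtx), sp.coo_matrix(cm.counts))
    meta.write_text(
        json.dumps(
            {"lag_ns": cm.lag_ns, "n_states": cm.n_states, "symmetrized": cm.symmetrized},
            indent=2,
        )
    )
    return [mtx, meta]


def load_count_matrix(prefix) -> CountMatrix:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    counts = np.asarray(mmread(str(prefix.with_suffix(".mtx"))).todense())
    return CountMatrix(counts=counts, lag_ns=meta["lag_ns"], symmetrized=meta["symmetrized"])


def save_model(model: MarkovModel, prefix) -> list[Path]:
    """Write T as MatrixMarket plus stationary vector / metadata JSON."""
    prefix = Path(prefix)
    mtx = prefix.with_suffix(".mtx")
    meta = prefix.with_suffix(".json")
    mmwrite(str(mtx), sp.coo_matrix(model.transition_matrix))
    meta.write_text(
        json.dumps(
            {
                "lag_ns": model.lag_ns,
                "n_states": model.n_states,
                "stationary": model.stationary.tolist(),
                "state_representatives": {
                    str(s): np.asarray(f).tolist() for s, f in model.state_representatives.items()
                },
            }
        )
    )
    return [mtx, meta]


def load_model(prefix) -> MarkovModel:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    t = np.asarray(mmread(str(prefix.with_suffix(".mtx"))).todense())
    reps = {int(s): np.asarray(f, int) for s, f in meta["state_representatives"].items()}
    return MarkovModel(
        transition_matrix=t,
        lag_ns=meta["lag_ns"],
        stationary=np.asarray(meta["stationary"]),
        state_representatives=reps,
    )


def save_dtraj(dtraj: DiscreteTrajectorySet, path) -> None:
    dtraj.to_csv(path)


def load_dtraj(path, frame_interval_ns: float, n_states: int | None = None) -> DiscreteTrajectorySet:
    df = pd.read_csv(path)
    for col in ("trajectory_id", "state"):
        if col not in df.columns:
            raise EstimationError(f"{path}: missing column {col!r}")
    states = df["state"].to_numpy(int)
    if n_states is None:
        n_states = int(states.max()) + 1 if states.size else 0
    return DiscreteTrajectorySet(
        state_labels=states,
        trajectory_ids=df["trajectory_id"].to_numpy(int),
        n_states=n_states,
        frame_interval_ns=frame_interval_ns,
    )
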