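"""Log file formats and run manifests.

Episode logs and hidden-state traces are tidy tables (one row per step).
The columnar Parquet format is the default store (the 64-wide hidden traces
stay fast to read); CSV is supported for interchange and inspection.  Angles
are stored in degrees, positions in metres, and the step index is 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EPISODE_COLUMNS",
    "TRACE_COLUMNS",
    "SCHEMA_VERSION",
    "write_episodes",
    "read_episodes",
    "write_traces",
    "read_traces",
    "RunManifest",
]

SCHEMA_VERSION = 1

#: EpisodeRecord column dictionary (name -> description).
EPISODE_COLUMNS = {
    "episode_id": "integer episode identifier",
    "regime": "wind/sparsity regime name",
    "step": "0-based environment step (25 steps/s)",
    "t": "episode time, s",
    "x": "agent x, m", "y": "agent y, m",
    "heading_deg": "head direction, deg anticlockwise from +x",
    "course_deg": "course direction of realized displacement, deg",
    "dx": "realized x displacement this step, m",
    "dy": "realized y displacement this step, m",
    "wind_x": "ground-frame wind x, m/s",
    "wind_y": "ground-frame wind y, m/s",
    "wx_ego": "egocentric wind x, m/s",
    "wy_ego": "egocentric wind y, m/s",
    "odour": "sensed odour concentration, a.u.",
    "turn": "turn action in [-1, 1]",
    "move": "move action in [0, 1]",
    "reward": "scalar reward",
    "stray": "distance to nearest puff, m",
    "distance": "distance to source, m",
    "outcome": "episode outcome (success/stray_fail/timeout)",
}

#: NeuralTrace columns: alignment keys plus the 64 hidden units.
TRACE_COLUMNS = ["episode_id", "step"] + [f"h{i:02d}" for i in range(64)]


def _check_schema(df: pd.DataFrame, expected, what: str):
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(
            f"{what} log schema mismatch: missing column(s) {missing}")


def _write(df: pd.DataFrame, path):
    path = Path(path)
    if path.suffix == ".csv":
        df.to_csv(path, index=False)
    else:
        df.to_parquet(path, index=False)


def _read(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".csv":
        return pd.read_csv(path)
    return pd.read_parquet(path)


def write_episodes(df: pd.DataFrame, path) -> None:
    """Write an EpisodeRecord table (schema-checked)."""
    _check_schema(df, EPISODE_COLUMNS, "episode")
    _write(df, path)


def read_episodes(path) -> pd.DataFrame:
    df = _read(path)
    _check_schema(df, EPISODE_COLUMNS, "episode")
    return df


def traces_to_table(traces: np.ndarray, episode_ids, steps) -> pd.DataFrame:
    """Pack a (T, 64) hidden-state array into the tidy trace table."""
    df = pd.DataFrame(np.asarray(traces),
                      columns=[f"h{i:02d}" for i in range(64)])
    df.insert(0, "step", np.asarray(steps))
    df.insert(0, "episode_id", np.asarray(episode_ids))
    return df


def write_traces(df: pd.DataFrame, path) -> None:
    """Write a NeuralTrace table (schema-checked)."""
    _check_schema(df, TRACE_COLUMNS, "trace")
    _write(df, path)


def read_traces(path) -> pd.DataFrame:
    df = _read(path)
    _check_schema(df, TRACE_COLUMNS, "trace")
    return df


@dataclass
class RunManifest:
    """Reproducibility record for one run: the config snapshot, the master
    seed and derived sub-stream seeds, the code version, and an inventory of
    every file the run produced."""

    config: dict
    master_seed: int
    substream_seeds: dict = field(default_factory=dict)
    version: str = ""
    outputs: list = field(default_factory=list)
    schema_version: int = SCHEMA_VERSION

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)
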