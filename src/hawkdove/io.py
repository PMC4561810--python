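"""Reading and writing game records and payoff configuration.

Game-record CSV schema (header mandatory, ``trial`` 1-based and contiguous
per dyad, actions coded ``A``/``R``)::

    pair_id,trial,action_p1,action_p2,payoff_p1,payoff_p2
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .game import Action, GameRecord, PayoffMatrix

__all__ = [
    "read_records",
    "write_records",
    "records_to_frame",
    "frame_to_records",
    "load_payoff_config",
    "save_payoff_config",
]

_COLUMNS = ["pair_id", "trial", "action_p1", "action_p2", "payoff_p1", "payoff_p2"]


def records_to_frame(records: Sequence[GameRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for tr in rec.trials:
            rows.append(
                {
                    "pair_id": rec.pair_id,
                    "trial": tr.t,
                    "action_p1": tr.a_1.code,
                    "action_p2": tr.a_2.code,
                    "payoff_p1": tr.pi_1,
                    "payoff_p2": tr.pi_2,
                }
            )
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_records(
    df: pd.DataFrame, matrix: Optional[PayoffMatrix] = None
) -> List[GameRecord]:
    """Validate a game-record table and build one :class:`GameRecord` per dyad.

    Malformed rows raise ``ValueError`` naming the offending row and column;
    payoffs inconsistent with ``matrix`` (when given) only warn.
    """
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    records = []
    for pair_id, sub in df.groupby("pair_id", sort=True):
        sub = sub.sort_values("trial")
        trials = sub["trial"].to_numpy()
        if not np.array_equal(trials, np.arange(1, len(sub) + 1)):
            raise ValueError(
                f"pair {pair_id!r}: trial indices must be 1..n without gaps, "
                f"got {trials[:5].tolist()}..."
            )
        actions = np.empty((len(sub), 2), dtype=np.int8)
        for j, col in enumerate(("action_p1", "action_p2")):
            for row_idx, code in zip(sub.index, sub[col]):
                try:
                    actions[sub.index.get_loc(row_idx), j] = Action.from_code(str(code))
                except ValueError as err:
                    raise ValueError(f"row {row_idx}, column {col}: {err}") from None
        payoffs = sub[["payoff_p1", "payoff_p2"]].to_numpy(dtype=float)
        rec = GameRecord(str(pair_id), actions, payoffs)
        if matrix is not None and not rec.payoffs_consistent(matrix):
            warnings.warn(
                f"pair {pair_id!r}: stored payoffs do not match the configured "
                "payoff matrix; record loaded as-is",
                stacklevel=2,
            )
        records.append(rec)
    return records


def read_records(
    path: Union[str, Path], matrix: Optional[PayoffMatrix] = None
) -> List[GameRecord]:
    """Read and validate a game-record CSV file."""
    df = pd.read_csv(path)
    return frame_to_records(df, matrix=matrix)


def write_records(records: Sequence[GameRecord], path: Union[str, Path]) -> None:
    records_to_frame(records).to_csv(path, index=False)


def load_payoff_config(path: Union[str, Path]) -> PayoffMatrix:
    """Load a payoff matrix from YAML or JSON (keys transfer, crash_cost, ...)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(data, dict):
        raise ValueError(f"payoff config {path} must be a mapping")
    return PayoffMatrix.from_dict(data)


def save_payoff_config(matrix: PayoffMatrix, path: Union[str, Path]) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(matrix.to_dict(), indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(matrix.to_dict(), sort_keys=False))
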