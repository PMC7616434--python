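"""CSV schemas for threshold datasets and result records.

The threshold-dataset schema (one row per tick): ``tick_id``,
``distance_mm``, ``threshold_voltage_V``, ``polarity`` ('+' or '-'),
``humidity_pct``.  Units live in the column names; comma-separated, header
row, UTF-8, '.' decimal.
"""

from __future__ import annotations

import json
from typing import Union

import pandas as pd

THRESHOLD_COLUMNS = (
    "tick_id",
    "distance_mm",
    "threshold_voltage_V",
    "polarity",
    "humidity_pct",
)


def load_threshold_dataset(path) -> pd.DataFrame:
    """Read a threshold dataset CSV, checking the schema."""
    df = pd.read_csv(path)
    missing = [c for c in ("distance_mm", "threshold_voltage_V") if c not in df.columns]
    if missing:
        raise ValueError(f"threshold dataset is missing columns: {missing}")
    return df


def save_threshold_dataset(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def dump_json(obj: Union[dict, list], path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)
        fh.write("\n")
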