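"""Reading and writing sample tables, metadata sidecars and configs.

A SampleTable travels as a plain CSV (one row per sample, empty fields for
missing gaze/pupil values) together with a small YAML sidecar holding the
recording metadata the analysis needs: sampling rate (Hz), horizontal screen
midpoint (px) and gaze mode (constrained/free).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .design import CONDITIONS, DEFAULT_SCREEN_MIDPOINT_PX
from .simulate import SimConfig

REQUIRED_COLUMNS = (
    "participant_id",
    "trial_index",
    "condition",
    "critical_position",
    "critical_direction",
    "time_ms",
    "gaze_x_px",
    "pupil_au",
    "valid",
)

DEFAULT_METADATA = {
    "sampling_rate_hz": 100,
    "screen_midpoint_px": DEFAULT_SCREEN_MIDPOINT_PX,
    "gaze_mode": "constrained",
}

PathLike = Union[str, os.PathLike]


def metadata_path_for(path: PathLike) -> Path:
    return Path(path).with_suffix(".meta.yaml")


def write_metadata(metadata: Mapping, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(metadata), fh, sort_keys=True)


def read_metadata(path: PathLike) -> dict:
    with open(path) as fh:
        meta = yaml.safe_load(fh) or {}
    out = dict(DEFAULT_METADATA)
    out.update(meta)
    return out


def write_samples(table: pd.DataFrame, path: PathLike,
                  metadata: Optional[Mapping] = None) -> None:
    """Write a SampleTable CSV plus its ``.meta.yaml`` sidecar.

    Missing samples are written as empty fields; row order is preserved
    (the simulator emits participant, trial, time order).
    """
    meta = dict(DEFAULT_METADATA)
    meta.update(table.attrs)
    if metadata:
        meta.update(metadata)
    out = table.copy()
    out["valid"] = out["valid"].astype(int)
    out.to_csv(path, index=False, na_rep="")
    write_metadata(meta, metadata_path_for(path))


def read_samples(path: PathLike, metadata: Optional[Mapping] = None) -> pd.DataFrame:
    """Read a SampleTable CSV, validate it, and attach recording metadata.

    Metadata is taken from the ``.meta.yaml`` sidecar when present, then
    overridden by the ``metadata`` argument.  Rows with missing gaze or pupil
    values are flagged invalid, never dropped.

    Raises
    ------
    ValueError
        On missing required columns, non-monotone time within a trial, or an
        unknown condition label.
    """
    table = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"sample table is missing required columns: {missing}")

    meta = dict(DEFAULT_METADATA)
    sidecar = metadata_path_for(path)
    if sidecar.exists():
        meta.update(read_metadata(sidecar))
    if metadata:
        meta.update(metadata)

    unknown = set(table["condition"].unique()) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown condition labels: {sorted(unknown)}")

    table["valid"] = table["valid"].astype(bool)
    # a sample without a measurement cannot count as valid
    table.loc[table["gaze_x_px"].isna() | table["pupil_au"].isna(), "valid"] = False

    for (pid, trial), grp in table.groupby(
        ["participant_id", "trial_index"], observed=True, sort=False
    ):
        dt = np.diff(grp["time_ms"].to_numpy())
        if len(dt) and not np.all(dt > 0):
            raise ValueError(
                f"time_ms not strictly increasing within trial {trial} of "
                f"participant {pid}"
            )

    table["condition"] = table["condition"].astype("category")
    table["participant_id"] = table["participant_id"].astype("category")
    table.attrs.update(meta)
    return table


def write_config(config: SimConfig, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def read_config(path: PathLike) -> SimConfig:
    with open(path) as fh:
        return SimConfig.from_dict(yaml.safe_load(fh))
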