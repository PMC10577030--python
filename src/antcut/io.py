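"""CSV and JSON plumbing for traces, tables and ground-truth sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .traces import ForceTrace

TRACE_COLUMNS = ["time_s", "raw_reading", "motor_pos_mm", "pass"]


def write_trace_csv(trace: ForceTrace, path: str | Path) -> None:
    pd.DataFrame({
        "time_s": trace.time,
        "raw_reading": trace.raw_reading,
        "motor_pos_mm": trace.motor_pos_mm,
        "pass": trace.pass_label,
    }).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> ForceTrace:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace file {path} is missing columns {sorted(missing)}")
    labels = df["pass"].unique()
    if len(labels) != 1:
        raise ValueError(f"trace file {path} mixes pass labels {list(labels)}")
    return ForceTrace(
        time=df["time_s"].to_numpy(),
        raw_reading=df["raw_reading"].to_numpy(),
        motor_pos_mm=df["motor_pos_mm"].to_numpy(),
        pass_label=str(labels[0]),
    )


def read_calibration_csv(path: str | Path, g: float = 9.81) -> pd.DataFrame:
    """Calibration table with either a force_N or a mass_g column."""
    df = pd.read_csv(path)
    if "force_N" not in df.columns:
        if "mass_g" not in df.columns:
            raise ValueError(f"{path}: need a force_N or mass_g column")
        df = df.assign(force_N=df["mass_g"] * 1e-3 * g)
    if "reading" not in df.columns:
        raise ValueError(f"{path}: need a reading column")
    return df[["force_N", "reading"]]


def write_ground_truth_json(truth: dict, path: str | Path) -> None:
    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    Path(path).write_text(json.dumps(truth, indent=2, default=_default) + "\n")
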