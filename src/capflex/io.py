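"""Readers and writers for traces, calibration tables, titrations and results.

Trace files are plain comma-separated text with a header row: a ``time_s``
column and one ``signal_<channel>_fu`` column per detector channel.
Multi-channel acquisitions (e.g. Alexa488 + ThT) live as sibling columns in
one file and are analyzed as independent traces.  Result objects are
serialized to JSON; floats survive a round trip losslessly (shortest-repr
encoding is exact for binary64).
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .types import (
    BaselineResult,
    BindingModel,
    CalibrationCurve,
    CapillarySystem,
    FormatError,
    PeakTable,
    SyntheticGroundTruth,
    Trace,
)

TIME_COLUMN = "time_s"


def _signal_column(channel: str) -> str:
    return f"signal_{channel}_fu"


def read_trace(path: str | Path, channel: str = "alexa488", **trace_kw: Any) -> Trace:
    """Read one channel of a comma-separated trace file.

    Raises :class:`FormatError` when the time or requested signal column is
    missing, and :class:`ValidationError` (from ``Trace``) when time is not
    strictly increasing — the offending index is named, nothing is sorted.
    """
    path = Path(path)
    df = pd.read_csv(path)
    col = _signal_column(channel)
    missing = [c for c in (TIME_COLUMN, col) if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)}"
        )
    return Trace(df[TIME_COLUMN].to_numpy(float), df[col].to_numpy(float),
                 channel=channel, **trace_kw)


def available_channels(path: str | Path) -> list[str]:
    """Channel labels present in a trace file."""
    cols = pd.read_csv(path, nrows=0).columns
    return [c[len("signal_"):-len("_fu")] for c in cols
            if c.startswith("signal_") and c.endswith("_fu")]


def write_trace(traces: Trace | list[Trace], path: str | Path) -> None:
    """Write one or more traces sharing a time grid to a CSV file."""
    if isinstance(traces, Trace):
        traces = [traces]
    t0 = traces[0]
    data: dict[str, np.ndarray] = {TIME_COLUMN: t0.time}
    for tr in traces:
        if tr.time.shape != t0.time.shape or not np.array_equal(tr.time, t0.time):
            raise FormatError("all channels in one file must share the time grid")
        data[_signal_column(tr.channel)] = tr.signal
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def read_calibration_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a standard-curve table with columns ``conc_um, baseline_fu``."""
    df = pd.read_csv(path)
    missing = [c for c in ("conc_um", "baseline_fu") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df["conc_um"].to_numpy(float), df["baseline_fu"].to_numpy(float)


def read_titration_table(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Read a binding titration: columns ``analyte_um, rh_nm[, rh_sd_nm]``."""
    df = pd.read_csv(path)
    missing = [c for c in ("analyte_um", "rh_nm") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    sd = df["rh_sd_nm"].to_numpy(float) if "rh_sd_nm" in df.columns else None
    return df["analyte_um"].to_numpy(float), df["rh_nm"].to_numpy(float), sd


# --- structured result serialization -------------------------------------

_RESULT_TYPES = {
    cls.__name__: cls
    for cls in (BaselineResult, CalibrationCurve, PeakTable, BindingModel,
                CapillarySystem, SyntheticGroundTruth)
}


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(result: Any, path: str | Path) -> None:
    """Serialize a result dataclass (or plain dict) to JSON."""
    if dataclasses.is_dataclass(result) and not isinstance(result, type):
        payload = {"_type": type(result).__name__}
        for f in dataclasses.fields(result):
            payload[f.name] = _jsonable(getattr(result, f.name))
    elif isinstance(result, dict):
        payload = {"_type": "dict", **_jsonable(result)}
    else:
        raise FormatError(f"cannot serialize object of type {type(result).__name__}")
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_results(path: str | Path) -> Any:
    """Re-read a result written by :func:`write_results`."""
    payload = json.loads(Path(path).read_text())
    kind = payload.pop("_type", None)
    if kind == "dict" or kind is None:
        return payload
    cls = _RESULT_TYPES.get(kind)
    if cls is None:
        raise FormatError(f"unknown result type {kind!r}")
    fields = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for k, v in payload.items():
        if k not in fields:
            raise FormatError(f"unexpected field {k!r} for {kind}")
        kwargs[k] = v
    # restore array-typed fields
    for f in dataclasses.fields(cls):
        v = kwargs.get(f.name)
        if isinstance(v, list) and f.name != "baseline_region" and not isinstance(v, np.ndarray):
            if f.name in ("concentrations", "baselines", "peak_times", "heights",
                          "integrals", "saturated"):
                kwargs[f.name] = np.asarray(v)
    if "baseline_region" in kwargs and isinstance(kwargs["baseline_region"], list):
        kwargs["baseline_region"] = tuple(kwargs["baseline_region"])
    return cls(**kwargs)
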