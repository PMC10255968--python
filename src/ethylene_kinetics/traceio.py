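"""Delimited-text I/O for traces, ripening tables and configurations.

Trace files are UTF-8 CSV with '.' decimals: metadata lines prefixed with
'#' (gas markers, units, free-form labels as JSON), then a ``time,value``
header and the samples.  Written traces round-trip bit-exactly through
:func:`read_trace`.  Times are converted to seconds on read when the file
declares minutes, unless ``keep_unit`` is set (day-scale ripening records
are conventionally kept in minutes).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .signal_model import SensorTrace


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def write_trace(trace: SensorTrace, path: str | Path) -> None:
    path = Path(path)
    meta = {k: v for k, v in trace.meta.items()}
    unit = meta.pop("time_unit", "s")
    lines = [f"# gas_in: {trace.gas_in!r}",
             f"# gas_out: {trace.gas_out!r}",
             f"# time_unit: {unit}",
             f"# meta: {json.dumps(meta, sort_keys=True)}",
             "time,value"]
    lines += [f"{float(t)!r},{float(v)!r}" for t, v in zip(trace.times, trace.values)]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_trace(path: str | Path, keep_unit: bool = True) -> SensorTrace:
    """Read a trace file.

    With ``keep_unit`` (default) times stay in the declared unit, recorded
    in ``meta['time_unit']``; otherwise minute-based files are converted to
    seconds.
    """
    path = Path(path)
    gas_in = gas_out = None
    unit = "s"
    meta: dict = {}
    times, values = [], []
    header_seen = False
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            key = key.strip()
            val = val.strip()
            try:
                if key == "gas_in":
                    gas_in = float(val)
                elif key == "gas_out":
                    gas_out = float(val)
                elif key == "time_unit":
                    if val not in ("s", "min"):
                        raise ValueError(f"unknown time unit {val!r}")
                    unit = val
                elif key == "meta":
                    meta = json.loads(val)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad header {line!r} ({exc})")
            continue
        if not header_seen:
            if line.replace(" ", "") != "time,value":
                raise ParseError(f"{path}:{lineno}: expected 'time,value' header")
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected two columns")
        try:
            times.append(float(parts[0]))
            values.append(float(parts[1]))
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric sample {line!r}")
        if len(times) >= 2 and times[-1] <= times[-2]:
            raise ParseError(f"{path}:{lineno}: non-increasing timestamp {parts[0]}")
    if gas_in is None or gas_out is None:
        raise ParseError(f"{path}: missing gas_in/gas_out marker header")
    if len(times) < 2:
        raise ParseError(f"{path}: fewer than two samples")

    times_arr = np.asarray(times)
    values_arr = np.asarray(values)
    if unit == "min" and not keep_unit:
        times_arr = times_arr * 60.0
        gas_in, gas_out = gas_in * 60.0, gas_out * 60.0
        unit = "s"
    meta["time_unit"] = unit
    return SensorTrace(times_arr, values_arr, gas_in, gas_out, meta)


def write_ripening_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_ripening_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "day" not in table.columns or "group" not in table.columns:
        raise ParseError(f"{path}: ripening table needs 'group' and 'day' columns")
    return table


def config_to_json(config, path: str | Path | None = None) -> str:
    """Serialize a generator/filter config dataclass to JSON (round-trips
    losslessly through :func:`config_from_json`)."""
    d = dataclasses.asdict(config)
    d["__type__"] = type(config).__name__
    text = json.dumps(d, sort_keys=True, indent=2, default=_jsonable)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def config_from_json(text_or_path: str | Path, registry: dict) -> object:
    """Rebuild a config dataclass from JSON given a {type name: class} map."""
    text = str(text_or_path)
    if not text.lstrip().startswith("{"):
        text = Path(text).read_text(encoding="utf-8")
    d = json.loads(text)
    cls = registry[d.pop("__type__")]
    for f in dataclasses.fields(cls):
        if f.name in d and isinstance(d[f.name], list):
            d[f.name] = tuple(d[f.name])
    return cls(**d)
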