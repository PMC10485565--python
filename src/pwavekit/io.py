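"""File I/O for sessions: flat-binary signals with JSON sidecars, CSV
hypnograms, event tables and spike trains.

Formats:

* signal: ``<label>.bin`` (little-endian, float64 by default) next to
  ``<label>.json`` holding ``{label, rate, t0, dtype, n_samples[, scale]}``.
* hypnogram: CSV ``epoch_index,state``.
* events: CSV ``time,onset,offset,amplitude,duration,state``.
* spikes: CSV ``unit_id,time,region``.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EVENT_COLUMNS, EventTable, Hypnogram, SignalTrace, SpikeTrain, STATES

__all__ = [
    "FormatError",
    "read_signals", "write_signals",
    "read_hypnogram", "write_hypnogram",
    "read_events", "write_events",
    "read_spikes", "write_spikes",
]

_DTYPES = {"float32": "<f4", "float64": "<f8", "int16": "<i2"}


class FormatError(ValueError):
    """Malformed on-disk session file."""


def write_signals(traces, path, dtype: str = "float64") -> None:
    """Write traces (iterable or dict of SignalTrace) to a directory.

    ``dtype='float64'`` round-trips bit-exactly; ``float32`` and
    ``int16`` (with a stored scale) are offered for compactness.
    """
    if isinstance(traces, dict):
        traces = list(traces.values())
    if dtype not in _DTYPES:
        raise FormatError(f"unsupported dtype {dtype!r}")
    labels = [tr.label for tr in traces]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate channel labels: {labels}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for tr in traces:
        meta = {"label": tr.label, "rate": tr.rate, "t0": tr.t0,
                "dtype": dtype, "n_samples": len(tr.samples)}
        x = tr.samples
        if dtype == "int16":
            peak = float(np.max(np.abs(x))) if len(x) else 1.0
            scale = peak / 32000.0 if peak > 0 else 1.0
            meta["scale"] = scale
            out = np.round(x / scale).astype("<i2")
        else:
            out = x.astype(_DTYPES[dtype])
        out.tofile(path / f"{tr.label}.bin")
        (path / f"{tr.label}.json").write_text(json.dumps(meta, indent=1))


def read_signals(path, labels=None) -> dict[str, SignalTrace]:
    """Read all (or selected) channels from a signal directory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    traces: dict[str, SignalTrace] = {}
    sidecars = sorted(path.glob("*.json"))
    if not sidecars:
        raise FormatError(f"no signal sidecars (*.json) in {path}")
    for sc in sidecars:
        meta = json.loads(sc.read_text())
        for key in ("label", "rate", "dtype", "n_samples"):
            if key not in meta:
                raise FormatError(f"{sc.name}: sidecar missing field {key!r}")
        if labels is not None and meta["label"] not in labels:
            continue
        if not isinstance(meta["rate"], (int, float)) or meta["rate"] <= 0:
            raise FormatError(f"{sc.name}: field 'rate' must be > 0, got {meta['rate']!r}")
        if meta["dtype"] not in _DTYPES:
            raise FormatError(f"{sc.name}: field 'dtype' has unsupported value {meta['dtype']!r}")
        raw = np.fromfile(sc.with_suffix(".bin"), dtype=_DTYPES[meta["dtype"]])
        if len(raw) != meta["n_samples"]:
            raise FormatError(
                f"{sc.name}: field 'n_samples' ({meta['n_samples']}) does not match "
                f"binary payload ({len(raw)} samples)")
        x = raw.astype(float)
        if meta["dtype"] == "int16":
            x = x * float(meta.get("scale", 1.0))
        traces[meta["label"]] = SignalTrace(x, float(meta["rate"]), meta["label"],
                                            float(meta.get("t0", 0.0)))
    return traces


def write_hypnogram(h: Hypnogram, path) -> None:
    pd.DataFrame({"epoch_index": np.arange(len(h)), "state": h.states}) \
        .to_csv(path, index=False)


def read_hypnogram(path, epoch_len: float = 4.0, t0: float = 0.0) -> Hypnogram:
    df = pd.read_csv(path, dtype={"state": str})
    if "state" not in df.columns:
        raise FormatError(f"{path}: missing 'state' column")
    states = df["state"].to_numpy()
    bad = ~np.isin(states, STATES)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise FormatError(f"{path}: unknown state label {states[row]!r} at row {row}")
    return Hypnogram(states, epoch_len=epoch_len, t0=t0)


def write_events(events: EventTable, path) -> None:
    events.df.to_csv(path, index=False)


def read_events(path, meta=None) -> EventTable:
    df = pd.read_csv(path, dtype={"state": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return EventTable(df, meta)


def write_spikes(trains: list[SpikeTrain], path) -> None:
    rows = [pd.DataFrame({"unit_id": tr.unit_id, "time": tr.times, "region": tr.region})
            for tr in trains]
    df = pd.concat(rows, ignore_index=True) if rows else \
        pd.DataFrame({"unit_id": [], "time": [], "region": []})
    df.to_csv(path, index=False)


def read_spikes(path) -> list[SpikeTrain]:
    df = pd.read_csv(path, dtype={"unit_id": str, "region": str})
    for col in ("unit_id", "time"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    trains = []
    for uid, grp in df.groupby("unit_id", sort=True):
        region = str(grp["region"].iloc[0]) if "region" in grp else ""
        trains.append(SpikeTrain(str(uid), np.sort(grp["time"].to_numpy(float)), region))
    return trains
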