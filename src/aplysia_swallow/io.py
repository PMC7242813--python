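"""Readers and writers for recordings, annotations, and result tables.

CSV signal layout: one column per channel named ``<name>:<role>``, plus a
``time`` column from which the sample rate is recovered. HDF5 layout: one
dataset per channel (attribute ``role``), file attributes ``sample_rate``
and ``t0``. Both round-trip bit-exactly at float64 precision.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import Channel, FormatError, ForceSegmentation, PairedAnimalTable, Recording, SwallowAnnotation

_COLUMN_RE = re.compile(r"^(?P<name>.+):(?P<role>nerve|emg|force)$")


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> Path:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        cols = {"time": rec.times}
        for c in rec.channels:
            cols[f"{c.name}:{c.role}"] = c.data
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["sample_rate"] = rec.sample_rate
            f.attrs["t0"] = rec.t0
            for i, c in enumerate(rec.channels):
                ds = f.create_dataset(c.name, data=c.data)
                ds.attrs["role"] = c.role
                ds.attrs["order"] = i
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        df = pd.read_csv(path)
        if "time" not in df.columns:
            raise FormatError(f"{path}: no 'time' column, sample rate unknown")
        t = df["time"].to_numpy(dtype=float)
        if len(t) < 2:
            raise FormatError(f"{path}: need at least two samples to infer sample rate")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise FormatError(f"{path}: time column is not uniformly sampled")
        channels = []
        for col in df.columns:
            if col == "time":
                continue
            m = _COLUMN_RE.match(col)
            if m is None:
                raise FormatError(f"{path}: column {col!r} is not '<name>:<role>'")
            channels.append(Channel(m["name"], m["role"], df[col].to_numpy(dtype=float)))
        return Recording(channels, sample_rate=1.0 / float(dt[0]), t0=float(t[0]))
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "sample_rate" not in f.attrs:
                raise FormatError(f"{path}: missing sample_rate attribute")
            sr = float(f.attrs["sample_rate"])
            t0 = float(f.attrs.get("t0", 0.0))
            items = sorted(f.items(), key=lambda kv: int(kv[1].attrs.get("order", 0)))
            channels = [Channel(name, str(ds.attrs.get("role", "nerve")), ds[()])
                        for name, ds in items]
        return Recording(channels, sample_rate=sr, t0=t0)
    raise ValueError(f"unknown format {fmt!r}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


# ---------------------------------------------------------------- annotations

_ANN_COLS = ["animal", "condition", "cycle_start", "cycle_end", "inward_start", "inward_end"]


def write_annotations(annotations: list[SwallowAnnotation], path: str | Path) -> Path:
    rows = []
    for a in annotations:
        i, j = a.inward_movement if a.inward_movement is not None else (np.nan, np.nan)
        rows.append((a.animal, a.condition, a.cycle_window[0], a.cycle_window[1], i, j))
    pd.DataFrame(rows, columns=_ANN_COLS).to_csv(path, index=False)
    return Path(path)


def read_annotations(path: str | Path) -> list[SwallowAnnotation]:
    df = pd.read_csv(path)
    missing = [c for c in _ANN_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation columns {missing}")
    out = []
    for _, r in df.iterrows():
        inward = None
        if np.isfinite(r["inward_start"]) and np.isfinite(r["inward_end"]):
            inward = (float(r["inward_start"]), float(r["inward_end"]))
        out.append(SwallowAnnotation(str(r["animal"]), str(r["condition"]),
                                     (float(r["cycle_start"]), float(r["cycle_end"])),
                                     inward))
    return out


# ----------------------------------------------------------------- spikes/bursts

def write_spikes(trains: dict[str, "np.ndarray"], path: str | Path) -> Path:
    """Write unit spike trains as a two-column CSV (unit, time_s)."""
    rows = [(unit, t) for unit in sorted(trains) for t in np.asarray(trains[unit])]
    pd.DataFrame(rows, columns=["unit", "time_s"]).to_csv(path, index=False)
    return Path(path)


def read_spikes(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {unit: g["time_s"].to_numpy(dtype=float)
            for unit, g in df.groupby("unit", sort=True)}


# ----------------------------------------------------------------- events

_EVENT_COLS = ["animal", "swallow", "e1", "e2", "e3", "e4", "e5", "v_end"]


def write_manual_events(rows: list[tuple[str, int, ForceSegmentation]], path: str | Path) -> Path:
    recs = []
    for animal, swallow, seg in rows:
        recs.append((animal, swallow,
                     np.nan if seg.e1 is None else seg.e1,
                     np.nan if seg.e2 is None else seg.e2,
                     seg.e3, seg.e4, seg.e5,
                     np.nan if seg.v_end is None else seg.v_end))
    pd.DataFrame(recs, columns=_EVENT_COLS).to_csv(path, index=False)
    return Path(path)


def read_manual_events(path: str | Path) -> list[tuple[str, int, ForceSegmentation]]:
    df = pd.read_csv(path)
    missing = [c for c in _EVENT_COLS[:7] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing event columns {missing}")
    out = []
    for _, r in df.iterrows():
        def opt(key: str) -> float | None:
            return None if key not in r or not np.isfinite(r[key]) else float(r[key])
        seg = ForceSegmentation(e3=float(r["e3"]), e4=float(r["e4"]), e5=float(r["e5"]),
                                e1=opt("e1"), e2=opt("e2"), v_end=opt("v_end"))
        out.append((str(r["animal"]), int(r["swallow"]), seg))
    return out


# ----------------------------------------------------------------- results

def write_results(tables: list[PairedAnimalTable], reports: dict | None,
                  outdir: str | Path) -> list[Path]:
    """Write one CSV per paired table plus a JSON statistics report.

    Returns the written paths; an empty input writes nothing and succeeds.
    """
    outdir = Path(outdir)
    written: list[Path] = []
    if tables:
        outdir.mkdir(parents=True, exist_ok=True)
    for table in tables:
        safe = re.sub(r"[^A-Za-z0-9._-]+", "_", table.measure)
        path = outdir / f"{safe}.csv"
        df = table.data.rename(columns={"n_unloaded": "n_u", "n_loaded": "n_l"})
        df[["animal", "unloaded", "loaded", "n_u", "n_l"]].to_csv(path, index=False)
        written.append(path)
    if reports is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / "statistics.json"
        path.write_text(json.dumps(reports, indent=2, sort_keys=True, default=_jsonify))
        written.append(path)
    return written


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_paired_table(path: str | Path, measure: str | None = None) -> PairedAnimalTable:
    df = pd.read_csv(path).rename(columns={"n_u": "n_unloaded", "n_l": "n_loaded"})
    return PairedAnimalTable(measure or Path(path).stem, df)
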