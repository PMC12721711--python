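"""Plain-text file formats: trace CSVs, metric tables, LN-model containers.

Traces are two-column CSV (time_s, value) with a single header comment line
carrying JSON metadata (dt, mean level, seed, ...).  Values are written with
17 significant digits so a write-read round trip is bit exact.  LN models
are stored as one JSON document holding the filter taps, dt, the bin table
of the nonlinearity, the baseline and free-form provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .ln import LinearFilter, LNModel, StaticNonlinearity
from .stimulus import StimulusTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_table",
    "read_table",
    "save_model",
    "load_model",
]

_MAGIC = "# retinaln-trace "


def write_trace(
    path,
    values: np.ndarray | StimulusTrace,
    dt: float | None = None,
    metadata: dict | None = None,
) -> None:
    """Write a trace (or StimulusTrace) as commented-header CSV."""
    if isinstance(values, StimulusTrace):
        meta = {"mean_level": values.mean_level, **values.metadata}
        dt = values.dt
        data = values.values
    else:
        if dt is None:
            raise ParameterError("dt is required for bare arrays")
        meta = dict(metadata or {})
        data = np.asarray(values, dtype=float)
    meta["dt"] = dt
    t = np.arange(data.size) * dt
    with open(path, "w") as fh:
        fh.write(_MAGIC + json.dumps(meta, sort_keys=True) + "\n")
        fh.write("time_s,value\n")
        for ti, vi in zip(t, data):
            fh.write(f"{ti:.17g},{vi:.17g}\n")


def read_trace(path):
    """Read a trace CSV.

    Returns a :class:`StimulusTrace` when the header carries a mean level,
    otherwise ``(values, dt, metadata)``.  Malformed or non-finite rows are
    reported with their line number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith(_MAGIC):
            raise ParameterError(f"{path.name}: not a retinaln trace file")
        meta = json.loads(header[len(_MAGIC):])
        colnames = fh.readline().strip()
        if colnames != "time_s,value":
            raise ParameterError(f"{path.name}: unexpected columns {colnames!r}")
        values = []
        for lineno, line in enumerate(fh, start=3):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            try:
                v = float(parts[1])
            except (IndexError, ValueError):
                raise ParameterError(f"{path.name}: malformed row at line {lineno}")
            if not np.isfinite(v):
                raise ParameterError(f"{path.name}: non-finite value at line {lineno}")
            values.append(v)
    data = np.asarray(values)
    dt = float(meta.pop("dt"))
    mean_level = meta.pop("mean_level", None)
    if mean_level is not None:
        return StimulusTrace(data, dt, float(mean_level), meta)
    return data, dt, meta


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic CSV dump of a metrics table (17 significant digits, no
    index, no timestamps)."""
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_model(model: LNModel, path, provenance: dict | None = None) -> None:
    """Serialize a fitted LN model to a single JSON container."""
    doc = {
        "format": "retinaln-ln-model-v1",
        "filter": {
            "taps": model.filter.taps.tolist(),
            "dt": model.filter.dt,
            "metadata": _plain(model.filter.metadata),
        },
        "nonlinearity": {
            "bin_centers": model.nonlinearity.bin_centers.tolist(),
            "bin_means": model.nonlinearity.bin_means.tolist(),
            "bin_counts": model.nonlinearity.bin_counts.tolist(),
        },
        "response_baseline": model.response_baseline,
        "provenance": _plain(provenance or {}),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def load_model(path) -> LNModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "retinaln-ln-model-v1":
        raise ParameterError(f"{Path(path).name}: not a retinaln LN-model file")
    filt = LinearFilter(
        np.asarray(doc["filter"]["taps"]),
        float(doc["filter"]["dt"]),
        doc["filter"].get("metadata", {}),
    )
    nl = StaticNonlinearity(
        np.asarray(doc["nonlinearity"]["bin_centers"]),
        np.asarray(doc["nonlinearity"]["bin_means"]),
        np.asarray(doc["nonlinearity"]["bin_counts"]),
    )
    return LNModel(filt, nl, float(doc["response_baseline"]))


def _plain(obj):
    """JSON-safe copy (numpy scalars/arrays to Python types)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
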