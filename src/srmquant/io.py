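"""CSV readers/writers for traces, concentration tables and results.

All writers prepend ``#``-prefixed header lines carrying the master seed
and a configuration hash, so every output is traceable to the run that
produced it; readers skip those lines transparently.
"""

from __future__ import annotations

import json
import hashlib
import warnings
from pathlib import Path

import pandas as pd
import yaml

from .simulate import TRACE_COLUMNS, TraceSet

__all__ = [
    "SchemaError",
    "read_traces",
    "write_traces",
    "read_table",
    "write_table",
    "load_config",
    "config_hash",
]


class SchemaError(ValueError):
    """An input file does not carry the expected columns."""


def _header_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def write_table(frame: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a CSV with optional ``# key=value`` header comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        frame.to_csv(fh, index=False)


def read_table(path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (comment lines skipped)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty file", stacklevel=2)
        frame = pd.DataFrame(columns=required or [])
    if required:
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    return frame


def write_traces(traces: TraceSet, path, meta: dict | None = None) -> None:
    write_table(traces.frame, path, meta)


def read_traces(path, validate: bool = True) -> TraceSet:
    """Read a long-format trace CSV; unknown columns are preserved.

    Raises :class:`SchemaError` naming any missing mandatory column and a
    format error on a non-monotone time grid (via TraceSet validation).
    """
    frame = read_table(path, required=TRACE_COLUMNS)
    if frame.empty:
        warnings.warn(f"{path}: no trace rows", stacklevel=2)
        return TraceSet(frame, validate=False)
    try:
        return TraceSet(frame, validate=validate)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def load_config(path) -> dict:
    """Load a JSON or YAML pipeline configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yml", ".yaml"):
        return yaml.safe_load(text)
    return json.loads(text)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
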