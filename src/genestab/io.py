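"""Reading and writing count tables and result records.

The canonical on-disk format for serial-transfer counts is a delimited text
table with header columns ``replicate, time_h, n_sampled, x_engineered``
(comma or tab, auto-detected).  Lines starting with ``#`` are metadata in
``key: value`` form and are preserved on round-trip of the canonical
(comma) dialect.  Results are written as YAML key-value documents embedding
the effective run configuration.
"""
from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import CountSeries

__all__ = ["read_counts", "write_counts", "write_result", "config_hash"]

COLUMNS = ["replicate", "time_h", "n_sampled", "x_engineered"]


def _parse_metadata(lines: list[str]) -> dict:
    meta = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if ":" in body:
            key, _, val = body.partition(":")
            try:
                meta[key.strip()] = json.loads(val.strip())
            except json.JSONDecodeError:
                meta[key.strip()] = val.strip()
    return meta


def read_counts(path) -> list[CountSeries]:
    """Read a counts table; returns one validated :class:`CountSeries` per replicate.

    Errors (missing columns, ``x > n``, non-increasing times, duplicate
    ``(replicate, time)`` rows) are reported with the 1-based line number of
    the offending data row.
    """
    path = Path(path)
    raw = path.read_text()
    lines = raw.splitlines()
    meta_lines = [ln for ln in lines if ln.startswith("#")]
    data_lines = [(i + 1, ln) for i, ln in enumerate(lines) if not ln.startswith("#") and ln.strip()]
    if not data_lines:
        raise ValueError(f"{path}: no data rows")
    meta = _parse_metadata(meta_lines)

    header_lineno, header = data_lines[0]
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(_io.StringIO("\n".join(ln for _, ln in data_lines)), sep=sep)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing} (header line {header_lineno})")
    df["_line"] = [lineno for lineno, _ in data_lines[1:]]

    bad = df[df["x_engineered"] > df["n_sampled"]]
    if len(bad):
        raise ValueError(
            f"{path}: x_engineered > n_sampled on line(s) {bad['_line'].tolist()}"
        )
    if (df["x_engineered"] < 0).any() or (df["n_sampled"] <= 0).any():
        bad = df[(df["x_engineered"] < 0) | (df["n_sampled"] <= 0)]
        raise ValueError(f"{path}: invalid counts on line(s) {bad['_line'].tolist()}")
    dup = df.duplicated(subset=["replicate", "time_h"], keep=False)
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (replicate, time_h) rows on line(s) {df.loc[dup, '_line'].tolist()}"
        )

    out = []
    for rep, grp in df.groupby("replicate", sort=False):
        t = grp["time_h"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            j = int(np.where(np.diff(t) <= 0)[0][0]) + 1
            raise ValueError(
                f"{path}: times not strictly increasing for replicate {rep!r} "
                f"at line {int(grp['_line'].iloc[j])}"
            )
        out.append(
            CountSeries(
                replicate=str(rep),
                t=t,
                n=grp["n_sampled"].to_numpy(int),
                x=grp["x_engineered"].to_numpy(int),
                meta=dict(meta),
            )
        )
    return out


def write_counts(path, series: list[CountSeries], metadata: dict | None = None) -> None:
    """Write count series as a canonical comma-delimited table.

    Metadata (plus anything shared in ``series[0].meta``) is written as
    ``# key: value`` comment lines above the header; values are JSON-encoded
    so the file round-trips through :func:`read_counts`.
    """
    path = Path(path)
    meta = dict(series[0].meta) if series and series[0].meta else {}
    if metadata:
        meta.update(metadata)
    frame = pd.concat([s.to_frame() for s in series], ignore_index=True)
    with path.open("w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {json.dumps(val, sort_keys=True)}\n")
        frame.to_csv(fh, index=False, columns=COLUMNS)


def config_hash(config: dict) -> str:
    """Short stable hash of an effective run configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_result(path, result, config: dict | None = None) -> None:
    """Write an estimate (or any mapping) as a YAML document with its config echo."""
    doc = result.to_dict() if hasattr(result, "to_dict") else dict(result)
    if config is not None:
        doc["config"] = config
        doc["config_hash"] = config_hash(config)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
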