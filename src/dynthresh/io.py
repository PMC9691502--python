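"""Plain-text file formats and run configuration.

Spike times: one time per line in ms at fixed precision 6, with '#'-prefixed
``key: value`` header lines carrying the generating parameters, seed, time
base and EOD period. ISIs: a single column with the unit tag in the header.
ACF and SCC sequences: two columns (lag, value). Run configs are YAML and
round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .errors import FormatError
from .model import ISISequence, SpikeTrain
from .noise import NoiseACF
from .theory import SCCSequence

__all__ = [
    "read_spike_times", "write_spike_times",
    "read_isis", "write_isis",
    "read_acf", "write_acf",
    "read_sccs", "write_sccs",
    "load_config", "save_config",
]

_TIME_FMT = "%.6f"


def _parse_header(lines):
    """Consume '#' header lines -> (metadata dict, first data line number)."""
    meta = {}
    start = 0
    for i, line in enumerate(lines):
        s = line.strip()
        if not s.startswith("#"):
            start = i
            break
        start = i + 1
        body = s.lstrip("#").strip()
        if ":" in body:
            key, _, val = body.partition(":")
            meta[key.strip()] = yaml.safe_load(val.strip())
    return meta, start


def write_spike_times(train: SpikeTrain, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# time_base: {train.time_base}\n")
        if train.eod_period:
            fh.write(f"# eod_period: {train.eod_period}\n")
        for key, val in train.meta.items():
            fh.write(f"# {key}: {json.dumps(val)}\n")
        fh.write("# unit: ms\n")
        np.savetxt(fh, train.times, fmt=_TIME_FMT)


def read_spike_times(path) -> SpikeTrain:
    path = Path(path)
    lines = path.read_text().splitlines()
    meta, start = _parse_header(lines)
    times = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        s = line.strip()
        if not s:
            continue
        try:
            t = float(s)
        except ValueError:
            raise FormatError(f"line {lineno}: not a number: {s!r}", line=lineno)
        if times and t <= times[-1]:
            raise FormatError(
                f"line {lineno}: spike time {t} not greater than previous", line=lineno
            )
        times.append(t)
    if len(times) < 2:
        raise FormatError(f"{path}: no spike train (fewer than 2 times)")
    time_base = meta.pop("time_base", "continuous")
    eod_period = meta.pop("eod_period", None)
    meta.pop("unit", None)
    return SpikeTrain(np.array(times), time_base=time_base,
                      eod_period=eod_period, meta=meta)


def write_isis(isis: ISISequence, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# unit: {isis.unit}\n")
        for key, val in isis.meta.items():
            fh.write(f"# {key}: {json.dumps(val)}\n")
        fmt = "%d" if isis.unit == "eod" else _TIME_FMT
        np.savetxt(fh, isis.intervals, fmt=fmt)


def read_isis(path) -> ISISequence:
    path = Path(path)
    lines = path.read_text().splitlines()
    meta, start = _parse_header(lines)
    unit = meta.pop("unit", "ms")
    vals = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        s = line.strip()
        if not s:
            continue
        try:
            vals.append(float(s))
        except ValueError:
            raise FormatError(f"line {lineno}: not a number: {s!r}", line=lineno)
    if not vals:
        raise FormatError(f"{path}: empty ISI file")
    return ISISequence(np.array(vals), unit=unit, meta=meta)


def write_acf(acf: NoiseACF, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# normalized: {str(acf.normalized).lower()}\n")
        fh.write("# columns: lag R_k\n")
        for k, val in enumerate(acf.values):
            fh.write(f"{k}\t{val:.12g}\n")


def read_acf(path) -> NoiseACF:
    path = Path(path)
    lines = path.read_text().splitlines()
    meta, start = _parse_header(lines)
    vals = _read_two_column(lines, start, path)
    return NoiseACF(vals, normalized=bool(meta.get("normalized", False)))


def write_sccs(sccs: SCCSequence, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# kind: {sccs.kind}\n")
        fh.write("# columns: lag rho_k\n")
        for k, val in enumerate(sccs.rho):
            fh.write(f"{k}\t{val:.12g}\n")


def read_sccs(path) -> SCCSequence:
    path = Path(path)
    lines = path.read_text().splitlines()
    meta, start = _parse_header(lines)
    vals = _read_two_column(lines, start, path)
    return SCCSequence(vals, kind=meta.get("kind", "theoretical"))


def _read_two_column(lines, start, path) -> np.ndarray:
    rows = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        s = line.strip()
        if not s:
            continue
        parts = s.split()
        if len(parts) != 2:
            raise FormatError(f"line {lineno}: expected 'lag value'", line=lineno)
        try:
            lag, val = int(parts[0]), float(parts[1])
        except ValueError:
            raise FormatError(f"line {lineno}: not numeric: {s!r}", line=lineno)
        if lag != len(rows):
            raise FormatError(f"line {lineno}: lags must be consecutive from 0",
                              line=lineno)
        rows.append(val)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return np.array(rows)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
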