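"""CSV readers and writers for count and censored-lifetime samples.

Conventions: comma-separated, UTF-8, LF line endings, header row required.
Count files have a single column; censored samples use columns
``time,event`` with ``event`` in {0, 1} (1 = observed, 0 = right-censored).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .inference import CensoredSample

__all__ = ["read_counts", "write_counts", "read_censored", "write_censored"]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def read_counts(path) -> np.ndarray:
    """Read a single-column count file (header required)."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    out = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        try:
            v = float(raw.strip())
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: not a number: {raw!r}") from None
        if v < 0 or v != int(v):
            raise ParseError(f"{path}: line {lineno}: counts must be non-negative integers")
        out.append(int(v))
    if not out:
        raise ParseError(f"{path}: no data rows")
    return np.asarray(out, dtype=np.int64)


def write_counts(path, counts, column: str = "count") -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as f:
        f.write(f"{column}\n")
        for v in np.asarray(counts).ravel():
            f.write(f"{int(v)}\n")


def read_censored(path) -> CensoredSample:
    """Read a ``time,event`` CSV into a :class:`CensoredSample`."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = [h.strip().lower() for h in lines[0].split(",")]
    if header[:2] != ["time", "event"]:
        raise ParseError(f"{path}: line 1: expected header 'time,event', got {lines[0]!r}")
    times, events = [], []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split(",")
        if len(parts) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 fields, got {len(parts)}")
        try:
            t = float(parts[0])
            d = int(parts[1])
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: malformed row: {raw!r}") from None
        if d not in (0, 1):
            raise ParseError(f"{path}: line {lineno}: event must be 0 or 1, got {d}")
        times.append(t)
        events.append(d)
    if len(times) < 2:
        raise ParseError(f"{path}: need at least 2 data rows")
    return CensoredSample(np.asarray(times), np.asarray(events))


def write_censored(path, sample: CensoredSample) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as f:
        f.write("time,event\n")
        for t, d in zip(sample.times, sample.events):
            ts = f"{int(t)}" if float(t).is_integer() else f"{t!r}"
            f.write(f"{ts},{int(d)}\n")


def series_to_csv(path, x, value, value_name: str = "value") -> None:
    """Export a numeric series (pmf table, hazard table, chain, ...) as CSV."""
    pd.DataFrame({"x": np.asarray(x), value_name: np.asarray(value)}).to_csv(
        path, index=False, lineterminator="\n"
    )
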