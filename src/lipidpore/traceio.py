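"""Delimited-text trace files with a self-describing header.

A trace file is plain TSV with a commented header that embeds the complete
generator metadata as JSON, so the simulation that produced it can be
reconstructed (and, given the stored seed, regenerated bit-identically):

    # lipidpore-trace v1
    # meta: {...json...}
    # n_samples: 31500
    # columns: time_s voltage_V current_A
    <tab-separated data rows>

Text was chosen over binary electrophysiology formats for auditability.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .synth import CurrentTrace

__all__ = ["TraceFormatError", "read_trace", "write_trace"]

_MAGIC = "# lipidpore-trace v1"


class TraceFormatError(ValueError):
    """Malformed trace file; the message names the offending line."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


def write_trace(trace: CurrentTrace, path) -> Path:
    """Write a trace; ``read_trace(write_trace(t)) == t`` exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write("# meta: " + json.dumps(trace.metadata, sort_keys=True) + "\n")
        fh.write(f"# n_samples: {len(trace.time_s)}\n")
        fh.write("# columns: time_s voltage_V current_A\n")
        np.savetxt(fh, np.column_stack([trace.time_s, trace.voltage_V, trace.current_A]),
                   fmt="%.17g", delimiter="\t")
    return path


def read_trace(path) -> CurrentTrace:
    """Read a trace file, validating header and column counts."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != _MAGIC:
        raise TraceFormatError("missing 'lipidpore-trace v1' magic header", 1)
    meta = None
    n_declared = None
    data_start = None
    for ln, line in enumerate(lines[1:], start=2):
        if not line.startswith("#"):
            data_start = ln
            break
        if line.startswith("# meta: "):
            try:
                meta = json.loads(line[len("# meta: "):])
            except json.JSONDecodeError as exc:
                raise TraceFormatError(f"bad metadata JSON ({exc})", ln) from exc
        elif line.startswith("# n_samples: "):
            n_declared = int(line[len("# n_samples: "):])
    if meta is None:
        raise TraceFormatError("missing '# meta:' header line", 1)
    if n_declared is None:
        raise TraceFormatError("missing '# n_samples:' header line", 1)
    if data_start is None:
        raise TraceFormatError("file contains no data rows", len(lines))

    rows = []
    for ln in range(data_start, len(lines) + 1):
        line = lines[ln - 1] if ln <= len(lines) else ""
        if ln > len(lines) or not line.strip():
            break
        parts = line.split("\t")
        if len(parts) != 3:
            raise TraceFormatError(f"expected 3 columns, got {len(parts)}", ln)
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise TraceFormatError(f"non-numeric value ({exc})", ln) from exc
    if len(rows) != n_declared:
        raise TraceFormatError(
            f"header declares {n_declared} samples but file has {len(rows)}",
            data_start + len(rows))
    arr = np.asarray(rows, dtype=float)
    return CurrentTrace(arr[:, 0], arr[:, 2], arr[:, 1], meta)
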