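"""The force-vs-position record of one unzipped molecule, and its TSV form.

``positions`` are bp unzipped along the chosen direction (monotone
non-decreasing), ``forces`` are the disruption forces recorded at those
positions, and ``time_s`` (optional) is the fork arrival time at each
position, from which per-bp dwell times follow by differencing.

File format: plain TSV with ``#key=value`` metadata comment lines, then a
header ``position_bp<TAB>force_pN[<TAB>time_s]``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np


@dataclass
class UnzipTrace:
    positions: np.ndarray
    forces: np.ndarray
    time_s: Optional[np.ndarray] = None
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        if self.time_s is not None:
            self.time_s = np.asarray(self.time_s, dtype=float)
            if self.time_s.shape != self.positions.shape:
                raise ValueError("time_s must match positions in length")
        if self.positions.shape != self.forces.shape:
            raise ValueError("positions and forces must have equal length")
        if self.positions.size and np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be monotone non-decreasing")
        if self.forces.size and not (np.all(np.isfinite(self.forces))
                                     and np.all(self.forces > 0)):
            raise ValueError("forces must be finite and positive")

    def __len__(self) -> int:
        return self.positions.size

    def copy(self) -> "UnzipTrace":
        return UnzipTrace(self.positions.copy(), self.forces.copy(),
                          None if self.time_s is None else self.time_s.copy(),
                          dict(self.meta))


def _format_meta_value(v: object) -> str:
    if isinstance(v, bool):
        return str(v).lower()
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _parse_meta_value(s: str) -> object:
    if s in ("true", "false"):
        return s == "true"
    if s == "None":
        return None
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s


def write_trace(trace: UnzipTrace, path: Union[str, Path]) -> None:
    path = Path(path)
    cols = ["position_bp", "force_pN"]
    data = [trace.positions, trace.forces]
    if trace.time_s is not None:
        cols.append("time_s")
        data.append(trace.time_s)
    buf = io.StringIO()
    for key in sorted(trace.meta):
        buf.write(f"#{key}={_format_meta_value(trace.meta[key])}\n")
    buf.write("\t".join(cols) + "\n")
    for row in zip(*data):
        buf.write("\t".join(f"{v:.6f}" for v in row) + "\n")
    path.write_text(buf.getvalue())


def read_trace(path: Union[str, Path]) -> UnzipTrace:
    path = Path(path)
    meta: Dict[str, object] = {}
    header = None
    rows = []
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = _parse_meta_value(value.strip())
            continue
        if header is None:
            header = line.split("\t")
            if header[:2] != ["position_bp", "force_pN"]:
                raise ValueError(f"{path}: unrecognized trace header {header!r}")
            continue
        rows.append([float(v) for v in line.split("\t")])
    if header is None or not rows:
        raise ValueError(f"{path}: empty or malformed trace file")
    arr = np.asarray(rows, dtype=float)
    if arr.shape[1] != len(header):
        raise ValueError(f"{path}: ragged trace file")
    time_s = arr[:, 2] if len(header) > 2 else None
    return UnzipTrace(arr[:, 0], arr[:, 1], time_s, meta)
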