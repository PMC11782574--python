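"""Text-based field and trajectory I/O.

Deformed meshes with per-element and per-node data are written as legacy
ASCII VTK unstructured grids (readable by ParaView); agent trajectories go
to tidy CSV; metrics reports and polylines to JSON.  All writers use 17
significant digits so write/read round-trips are lossless at double
precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VTKParseError",
    "write_vtk",
    "read_vtk",
    "write_trajectories_csv",
    "read_trajectories_csv",
    "write_report_json",
    "read_report_json",
    "write_polyline_json",
    "read_polyline_json",
]

_FMT = "%.17g"


class VTKParseError(ValueError):
    """Raised when a VTK file is malformed or truncated; names the section."""


def _fmt_row(vals) -> str:
    return " ".join(_FMT % v for v in vals)


def write_vtk(
    path,
    nodes: np.ndarray,
    quads: np.ndarray,
    cell_data: dict | None = None,
    point_data: dict | None = None,
    title: str = "foldax fields",
) -> None:
    """Write a quad mesh + data arrays as a legacy ASCII VTK file.

    ``cell_data`` / ``point_data`` map names to 1-D arrays (scalars) or
    (n, 2) arrays (vectors, padded with a zero z-component).
    """
    nodes = np.asarray(nodes, dtype=float)
    quads = np.asarray(quads, dtype=np.int64)
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(nodes)} double",
    ]
    for p in nodes:
        lines.append(_fmt_row([p[0], p[1], 0.0]))
    lines.append(f"CELLS {len(quads)} {5 * len(quads)}")
    for q in quads:
        lines.append("4 " + " ".join(str(int(n)) for n in q))
    lines.append(f"CELL_TYPES {len(quads)}")
    lines.extend("9" for _ in range(len(quads)))

    def emit_data(block: str, count: int, data: dict) -> None:
        lines.append(f"{block} {count}")
        for name, arr in data.items():
            arr = np.asarray(arr)
            if arr.shape[0] != count:
                raise ValueError(f"data array {name!r} has wrong length")
            if arr.ndim == 1:
                kind = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
                lines.append(f"SCALARS {name} {kind} 1")
                lines.append("LOOKUP_TABLE default")
                if kind == "int":
                    lines.extend(str(int(v)) for v in arr)
                else:
                    lines.extend(_FMT % v for v in arr)
            elif arr.ndim == 2 and arr.shape[1] == 2:
                lines.append(f"VECTORS {name} double")
                lines.extend(_fmt_row([v[0], v[1], 0.0]) for v in arr)
            else:
                raise ValueError(f"unsupported data shape for {name!r}: {arr.shape}")

    if cell_data:
        emit_data("CELL_DATA", len(quads), cell_data)
    if point_data:
        emit_data("POINT_DATA", len(nodes), point_data)
    Path(path).write_text("\n".join(lines) + "\n")


class _TokenStream:
    """Whitespace token stream with positional error context."""

    def __init__(self, text: str, path):
        self.tokens = text.split()
        self.pos = 0
        self.path = path

    def next(self, what: str) -> str:
        if self.pos >= len(self.tokens):
            raise VTKParseError(
                f"{self.path}: truncated file while reading {what} "
                f"(token {self.pos} of {len(self.tokens)})"
            )
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def next_int(self, what: str) -> int:
        tok = self.next(what)
        try:
            return int(tok)
        except ValueError as err:
            raise VTKParseError(
                f"{self.path}: expected integer for {what}, got {tok!r}"
            ) from err

    def next_float(self, what: str) -> float:
        tok = self.next(what)
        try:
            return float(tok)
        except ValueError as err:
            raise VTKParseError(
                f"{self.path}: expected number for {what}, got {tok!r}"
            ) from err

    def expect(self, keyword: str, what: str) -> None:
        tok = self.next(what)
        if tok != keyword:
            raise VTKParseError(
                f"{self.path}: expected {keyword!r} in {what}, got {tok!r}"
            )


def read_vtk(path) -> dict:
    """Read a legacy ASCII VTK unstructured quad grid written by write_vtk.

    Returns a dict with ``nodes`` (n, 2), ``quads`` (E, 4), ``cell_data``
    and ``point_data``; raises :class:`VTKParseError` on malformed or
    truncated input, naming the failing section.
    """
    text = Path(path).read_text()
    header, _, body = text.partition("DATASET")
    if "# vtk DataFile" not in header:
        raise VTKParseError(f"{path}: missing VTK header line")
    if "ASCII" not in header:
        raise VTKParseError(f"{path}: only ASCII VTK files are supported")
    ts = _TokenStream(body, path)
    ts.expect("UNSTRUCTURED_GRID", "dataset type")
    ts.expect("POINTS", "points section")
    n_pts = ts.next_int("point count")
    ts.next("points dtype")
    nodes = np.empty((n_pts, 2))
    for i in range(n_pts):
        nodes[i, 0] = ts.next_float(f"point {i} x")
        nodes[i, 1] = ts.next_float(f"point {i} y")
        ts.next_float(f"point {i} z")
    ts.expect("CELLS", "cells section")
    n_cells = ts.next_int("cell count")
    ts.next_int("cell list size")
    quads = np.empty((n_cells, 4), dtype=np.int64)
    for e in range(n_cells):
        npc = ts.next_int(f"cell {e} node count")
        if npc != 4:
            raise VTKParseError(f"{path}: cell {e} is not a quad ({npc} nodes)")
        for a in range(4):
            quads[e, a] = ts.next_int(f"cell {e} node {a}")
    ts.expect("CELL_TYPES", "cell types section")
    n_types = ts.next_int("cell type count")
    for e in range(n_types):
        code = ts.next_int(f"cell {e} type")
        if code != 9:
            raise VTKParseError(f"{path}: cell {e} has non-quad VTK type {code}")

    out = {"nodes": nodes, "quads": quads, "cell_data": {}, "point_data": {}}
    current = None
    count = 0
    while ts.pos < len(ts.tokens):
        tok = ts.next("data section keyword")
        if tok == "CELL_DATA":
            count = ts.next_int("cell data count")
            current = out["cell_data"]
        elif tok == "POINT_DATA":
            count = ts.next_int("point data count")
            current = out["point_data"]
        elif tok == "SCALARS":
            if current is None:
                raise VTKParseError(f"{path}: SCALARS outside a data section")
            name = ts.next("scalar name")
            kind = ts.next("scalar dtype")
            ts.next("scalar components")
            ts.expect("LOOKUP_TABLE", f"scalars {name}")
            ts.next("lookup table name")
            if kind == "int":
                current[name] = np.array(
                    [ts.next_int(f"{name}[{i}]") for i in range(count)],
                    dtype=np.int64,
                )
            else:
                current[name] = np.array(
                    [ts.next_float(f"{name}[{i}]") for i in range(count)]
                )
        elif tok == "VECTORS":
            if current is None:
                raise VTKParseError(f"{path}: VECTORS outside a data section")
            name = ts.next("vector name")
            ts.next("vector dtype")
            arr = np.empty((count, 2))
            for i in range(count):
                arr[i, 0] = ts.next_float(f"{name}[{i}] x")
                arr[i, 1] = ts.next_float(f"{name}[{i}] y")
                ts.next_float(f"{name}[{i}] z")
            current[name] = arr
        else:
            raise VTKParseError(f"{path}: unexpected keyword {tok!r} in data block")
    return out


# --------------------------------------------------------------------- #
# trajectories, reports, polylines
# --------------------------------------------------------------------- #

_TRAJ_COLUMNS = ["agent", "step", "x", "y", "theta", "sigma", "status"]


def write_trajectories_csv(path, records) -> pd.DataFrame:
    """Write per-agent per-step records as tidy CSV.

    ``records`` is an iterable of dicts (or a DataFrame) with columns
    agent, step, x, y, theta, sigma, status.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory records missing columns {missing}")
    df = df[_TRAJ_COLUMNS]
    df.to_csv(path, index=False, float_format=_FMT)
    return df


def read_trajectories_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: trajectory file missing columns {missing}")
    return df


def write_report_json(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report_json(path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"{path}: malformed report JSON: {err}") from err


def write_polyline_json(path, polylines: dict) -> None:
    """Write named polylines ({name: (n, 2) array}) as JSON."""
    payload = {
        name: [[float(p[0]), float(p[1])] for p in np.asarray(poly)]
        for name, poly in polylines.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_polyline_json(path) -> dict:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"{path}: malformed polyline JSON: {err}") from err
    return {name: np.asarray(poly, dtype=float) for name, poly in payload.items()}
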