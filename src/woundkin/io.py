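"""CSV dialects and readers/writers.

All interchange is UTF-8 CSV with a header row; lines starting with
``#`` are comments. Schemas are strict: a missing column, a non-numeric
cell, or a duplicate key row is an error naming the file line, never a
silently dropped row.

Dialects
--------
closure curves
    ``condition,replicate,time_h,gap_area`` (raw areas, normalized on
    read) or ``condition,replicate,time_h,gap_pct`` (pre-normalized).
fits
    ``condition,replicate,model,k1,k2,breakpoint_h,r_squared,sse,n_points``
    with empty fields for the absent k2/breakpoint of monophasic fits.
cells
    ``image_id,x_um,y_um,marker,positive`` with positive in {0, 1}.
edges
    ``image_id,edge_type,vertex_index,x_um,y_um`` with vertices ordered
    by index along the polyline.
"""

from __future__ import annotations

import csv
import io as _stdio
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .edge_band import CellRecord, EdgeGeometry
from .errors import SchemaError
from .kinetics import ClosureSeries, KineticsFit, normalize_gap

__all__ = [
    "read_closure_csv",
    "write_closure_csv",
    "write_fits_csv",
    "read_fits_csv",
    "read_cells_csv",
    "write_cells_csv",
    "read_edges_csv",
    "write_edges_csv",
    "read_mask",
]

PathLike = Union[str, Path]


def _read_rows(path: PathLike) -> Tuple[List[str], List[Tuple[int, List[str]]]]:
    """Parse a commented CSV; returns (header, [(line_number, fields), ...])."""
    numbered = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.lstrip().startswith("#"):
                continue
            fields = next(csv.reader(_stdio.StringIO(raw)))
            numbered.append((lineno, [f.strip() for f in fields]))
    if not numbered:
        raise SchemaError(f"{path}: empty file")
    (_, header), rows = numbered[0], numbered[1:]
    return header, rows


def _column_map(path: PathLike, header: Sequence[str], required: Sequence[str]) -> Dict[str, int]:
    idx = {name: i for i, name in enumerate(header)}
    missing = [c for c in required if c not in idx]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return idx


def _as_float(path: PathLike, lineno: int, column: str, value: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise SchemaError(
            f"{path}, line {lineno}: non-numeric value {value!r} in column {column}"
        ) from None


def read_closure_csv(path: PathLike) -> List[ClosureSeries]:
    """Read closure curves, grouping by (condition, replicate).

    Rows may arrive in any order; times are sorted ascending per series.
    Raw-area files are normalized to gap percent on read. Duplicate
    (condition, replicate, time) rows are an error.
    """
    header, rows = _read_rows(path)
    idx = _column_map(path, header, ["condition", "replicate", "time_h"])
    if "gap_area" in idx:
        value_col = "gap_area"
    elif "gap_pct" in idx:
        value_col = "gap_pct"
    else:
        raise SchemaError(f"{path}: need a gap_area or gap_pct column")
    seen: Dict[Tuple[str, str, float], int] = {}
    grouped: Dict[Tuple[str, str], List[Tuple[float, float]]] = {}
    for lineno, fields in rows:
        if len(fields) != len(header):
            raise SchemaError(f"{path}, line {lineno}: expected {len(header)} fields")
        cond = fields[idx["condition"]]
        rep = fields[idx["replicate"]]
        t = _as_float(path, lineno, "time_h", fields[idx["time_h"]])
        v = _as_float(path, lineno, value_col, fields[idx[value_col]])
        key = (cond, rep, t)
        if key in seen:
            raise SchemaError(
                f"{path}, line {lineno}: duplicate (condition, replicate, time) "
                f"also on line {seen[key]}"
            )
        seen[key] = lineno
        grouped.setdefault((cond, rep), []).append((t, v))
    out = []
    for (cond, rep), pts in grouped.items():
        pts.sort()
        times = np.array([p[0] for p in pts])
        vals = np.array([p[1] for p in pts])
        if value_col == "gap_area":
            out.append(
                normalize_gap(
                    ClosureSeries(condition=cond, replicate=rep, times=times, gap_area=vals)
                )
            )
        else:
            out.append(
                ClosureSeries(condition=cond, replicate=rep, times=times, gap_pct=vals)
            )
    return out


def write_closure_csv(series: Sequence[ClosureSeries], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["condition", "replicate", "time_h", "gap_pct"])
        for s in series:
            if not s.is_normalized:
                s = normalize_gap(s)
            for t, v in zip(s.times, s.gap_pct):
                w.writerow([s.condition, s.replicate, repr(float(t)), repr(float(v))])


_FIT_COLS = [
    "condition", "replicate", "model", "k1", "k2",
    "breakpoint_h", "r_squared", "sse", "n_points",
]


def write_fits_csv(
    fits: Sequence[Tuple[str, str, KineticsFit]], path: PathLike
) -> None:
    """Write (condition, replicate, fit) triples; absent k2/breakpoint blank."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_FIT_COLS)
        for cond, rep, f in fits:
            w.writerow(
                [
                    cond, rep, f.model, repr(f.k1),
                    "" if f.k2 is None else repr(f.k2),
                    "" if f.breakpoint_h is None else repr(f.breakpoint_h),
                    repr(f.r_squared), repr(f.sse), f.n_points,
                ]
            )


def read_fits_csv(path: PathLike) -> List[Tuple[str, str, KineticsFit]]:
    header, rows = _read_rows(path)
    idx = _column_map(path, header, _FIT_COLS)
    out = []
    for lineno, fields in rows:
        k2 = fields[idx["k2"]]
        tb = fields[idx["breakpoint_h"]]
        fit = KineticsFit(
            model=fields[idx["model"]],
            k1=_as_float(path, lineno, "k1", fields[idx["k1"]]),
            k2=None if k2 == "" else _as_float(path, lineno, "k2", k2),
            breakpoint_h=None if tb == "" else _as_float(path, lineno, "breakpoint_h", tb),
            intercept=math.nan,
            r_squared=_as_float(path, lineno, "r_squared", fields[idx["r_squared"]]),
            sse=_as_float(path, lineno, "sse", fields[idx["sse"]]),
            n_points=int(_as_float(path, lineno, "n_points", fields[idx["n_points"]])),
            fit_window=(math.nan, math.nan),
        )
        out.append((fields[idx["condition"]], fields[idx["replicate"]], fit))
    return out


def read_cells_csv(path: PathLike) -> List[CellRecord]:
    header, rows = _read_rows(path)
    idx = _column_map(path, header, ["image_id", "x_um", "y_um", "marker", "positive"])
    cells = []
    for lineno, fields in rows:
        pos = fields[idx["positive"]]
        if pos not in ("0", "1"):
            raise SchemaError(f"{path}, line {lineno}: positive must be 0 or 1, got {pos!r}")
        cells.append(
            CellRecord(
                image_id=fields[idx["image_id"]],
                x=_as_float(path, lineno, "x_um", fields[idx["x_um"]]),
                y=_as_float(path, lineno, "y_um", fields[idx["y_um"]]),
                marker=fields[idx["marker"]],
                positive=pos == "1",
            )
        )
    return cells


def write_cells_csv(cells: Sequence[CellRecord], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_id", "x_um", "y_um", "marker", "positive"])
        for c in cells:
            w.writerow([c.image_id, repr(c.x), repr(c.y), c.marker, int(c.positive)])


def read_edges_csv(path: PathLike) -> List[EdgeGeometry]:
    """Read edge polylines grouped by (image_id, edge_type).

    Vertices of one polyline are ordered by ``vertex_index``; a
    ``vertex_index`` that does not continue the previous row's run (a
    reset to 0) starts a new polyline under the same key, so an image
    may carry several fronts (e.g. the two borders of a scratch gap).
    """
    header, rows = _read_rows(path)
    idx = _column_map(path, header, ["image_id", "edge_type", "vertex_index", "x_um", "y_um"])
    polylines: List[Tuple[str, str, List[Tuple[float, float]]]] = []
    last_key = None
    last_index = None
    for lineno, fields in rows:
        key = (fields[idx["image_id"]], fields[idx["edge_type"]])
        vi = _as_float(path, lineno, "vertex_index", fields[idx["vertex_index"]])
        xy = (
            _as_float(path, lineno, "x_um", fields[idx["x_um"]]),
            _as_float(path, lineno, "y_um", fields[idx["y_um"]]),
        )
        if key != last_key or last_index is None or vi <= last_index:
            polylines.append((key[0], key[1], [xy]))
        else:
            polylines[-1][2].append(xy)
        last_key, last_index = key, vi
    return [
        EdgeGeometry(image_id=image_id, edge_type=edge_type, vertices=np.array(verts))
        for image_id, edge_type, verts in polylines
    ]


def write_edges_csv(edges: Sequence[EdgeGeometry], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_id", "edge_type", "vertex_index", "x_um", "y_um"])
        for e in edges:
            for i, (x, y) in enumerate(e.vertices):
                w.writerow([e.image_id, e.edge_type, i, repr(float(x)), repr(float(y))])


def read_mask(path: PathLike) -> np.ndarray:
    """Load a single-channel mask image (TIFF/PNG); nonzero is foreground."""
    import skimage.io

    img = skimage.io.imread(str(path))
    if img.ndim == 3:
        img = img[..., 0]
    return (np.asarray(img) != 0).astype(np.uint8)
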