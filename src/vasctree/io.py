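"""Readers and writers for vessel spatial graphs.

Two dialects are supported:

* ``amira_ascii`` — the AmiraMesh 3D ASCII ``HxSpatialGraph`` layout
  (``VERTEX { float[3] VertexCoordinates }``, ``EDGE { int[2] EdgeConnectivity,
  int NumEdgePoints }``, ``POINT { float[3] EdgePointCoordinates,
  float thickness }``). The thickness channel is interpreted as a radius in µm
  by default; pass ``thickness_is_diameter=True`` if a file stores diameters.
* ``tabular`` — two delimited text tables (``<base>_segments.csv`` and
  ``<base>_points.csv``) with one row per segment / per point.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import GraphError, Node, Segment, SpatialGraph

__all__ = ["read_spatial_graph", "write_spatial_graph", "ParseError"]


class ParseError(ValueError):
    """Raised when a spatial-graph file is malformed."""


# ---------------------------------------------------------------------------
# AmiraMesh ASCII
# ---------------------------------------------------------------------------

_SECTION_RE = re.compile(
    r"(VERTEX|EDGE|POINT)\s*\{\s*(float|int)(?:\[(\d+)\])?\s+(\w+)\s*\}\s*@(\d+)"
)
_DEFINE_RE = re.compile(r"define\s+(VERTEX|EDGE|POINT)\s+(\d+)")


def _parse_amira(path: Path, thickness_is_diameter: bool) -> SpatialGraph:
    text = path.read_text()
    if "AmiraMesh" not in text.split("\n", 1)[0]:
        raise ParseError(f"{path}: missing AmiraMesh header line")

    counts = {m.group(1): int(m.group(2)) for m in _DEFINE_RE.finditer(text)}
    for kind in ("VERTEX", "EDGE", "POINT"):
        if kind not in counts:
            raise ParseError(f"{path}: missing 'define {kind}' record")

    sections: dict[str, tuple[str, int, int]] = {}  # name -> (kind, width, marker)
    for m in _SECTION_RE.finditer(text):
        kind, _dtype, width, name, marker = m.groups()
        sections[name] = (kind, int(width or 1), int(marker))

    required = {
        "VertexCoordinates": ("VERTEX", 3),
        "EdgeConnectivity": ("EDGE", 2),
        "NumEdgePoints": ("EDGE", 1),
        "EdgePointCoordinates": ("POINT", 3),
    }
    for name, (kind, width) in required.items():
        if name not in sections:
            raise ParseError(f"{path}: missing section declaration for {name}")
        if sections[name][:2] != (kind, width):
            raise ParseError(f"{path}: unexpected declaration for {name}")
    thick_name = next(
        (n for n in ("thickness", "Thickness", "Radius", "radius") if n in sections), None
    )
    if thick_name is None:
        raise ParseError(f"{path}: no thickness/radius POINT section")

    # split the data blocks "@N ... values ..."
    blocks: dict[int, np.ndarray] = {}
    for m in re.finditer(r"^@(\d+)\s*$", text, flags=re.M):
        marker = int(m.group(1))
        start = m.end()
        nxt = re.search(r"^@\d+\s*$", text[start:], flags=re.M)
        chunk = text[start : start + nxt.start()] if nxt else text[start:]
        vals = chunk.split()
        try:
            blocks[marker] = np.array(vals, dtype=float)
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric data in block @{marker}") from exc

    def block(name: str, n_rows: int) -> np.ndarray:
        kind, width, marker = sections[name]
        if marker not in blocks:
            raise ParseError(f"{path}: data block @{marker} ({name}) missing")
        data = blocks[marker]
        if data.size != n_rows * width:
            raise ParseError(
                f"{path}: section {name} expects {n_rows * width} values, got {data.size}"
            )
        return data.reshape(n_rows, width) if width > 1 else data

    coords = block("VertexCoordinates", counts["VERTEX"])
    conn = block("EdgeConnectivity", counts["EDGE"]).astype(int)
    npts = block("NumEdgePoints", counts["EDGE"]).astype(int)
    if npts.sum() != counts["POINT"]:
        raise ParseError(
            f"{path}: NumEdgePoints sums to {npts.sum()} but POINT count is {counts['POINT']}"
        )
    pts = block("EdgePointCoordinates", counts["POINT"])
    thick = np.atleast_1d(block(thick_name, counts["POINT"]))
    if thickness_is_diameter:
        thick = thick / 2.0

    graph = SpatialGraph(metadata={"units": "um", "provenance": str(path)})
    for i, pos in enumerate(coords):
        graph.add_node(Node(id=i, position=pos))
    offset = 0
    for eid, ((a, b), n) in enumerate(zip(conn, npts)):
        if not (0 <= a < counts["VERTEX"] and 0 <= b < counts["VERTEX"]):
            raise ParseError(f"{path}: edge {eid} references unknown vertex ({a}, {b})")
        if n < 2:
            raise ParseError(f"{path}: edge {eid} has {n} points (< 2)")
        seg = Segment(
            id=eid,
            start_node=int(a),
            end_node=int(b),
            points=pts[offset : offset + n],
            radii=thick[offset : offset + n],
        )
        try:
            graph.add_segment(seg)
        except GraphError as exc:
            raise ParseError(f"{path}: edge {eid}: {exc}") from exc
        offset += n
    return graph


def _write_amira(graph: SpatialGraph, path: Path) -> None:
    node_ids = sorted(graph.nodes)
    node_index = {nid: i for i, nid in enumerate(node_ids)}
    seg_ids = sorted(graph.segments)
    n_points = graph.n_points

    lines = [
        "# AmiraMesh 3D ASCII 2.0",
        "",
        f"define VERTEX {len(node_ids)}",
        f"define EDGE {len(seg_ids)}",
        f"define POINT {n_points}",
        "",
        "Parameters {",
        '    ContentType "HxSpatialGraph"',
        "}",
        "",
        "VERTEX { float[3] VertexCoordinates } @1",
        "EDGE { int[2] EdgeConnectivity } @2",
        "EDGE { int NumEdgePoints } @3",
        "POINT { float[3] EdgePointCoordinates } @4",
        "POINT { float thickness } @5",
        "",
        "@1",
    ]
    fmt = "{:.17g}"
    for nid in node_ids:
        lines.append(" ".join(fmt.format(v) for v in graph.nodes[nid].position))
    lines += ["", "@2"]
    for sid in seg_ids:
        s = graph.segments[sid]
        lines.append(f"{node_index[s.start_node]} {node_index[s.end_node]}")
    lines += ["", "@3"]
    for sid in seg_ids:
        lines.append(str(graph.segments[sid].n_points))
    lines += ["", "@4"]
    for sid in seg_ids:
        for p in graph.segments[sid].points:
            lines.append(" ".join(fmt.format(v) for v in p))
    lines += ["", "@5"]
    for sid in seg_ids:
        for r in graph.segments[sid].radii:
            lines.append(fmt.format(r))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Tabular dialect
# ---------------------------------------------------------------------------


def _tabular_paths(path: Path) -> tuple[Path, Path]:
    base = str(path)
    for suffix in (".csv", ".tsv"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
    return Path(base + "_segments.csv"), Path(base + "_points.csv")


def _write_tabular(graph: SpatialGraph, path: Path) -> None:
    seg_path, pt_path = _tabular_paths(path)
    seg_rows, pt_rows = [], []
    for sid in sorted(graph.segments):
        s = graph.segments[sid]
        seg_rows.append(
            {
                "segment_id": sid,
                "start_node": s.start_node,
                "end_node": s.end_node,
                "n_points": s.n_points,
                "compartment": s.compartment if s.compartment is not None else "",
            }
        )
        for i, (p, r) in enumerate(zip(s.points, s.radii)):
            pt_rows.append(
                {
                    "segment_id": sid,
                    "point_index": i,
                    "x_um": p[0],
                    "y_um": p[1],
                    "z_um": p[2],
                    "radius_um": r,
                }
            )
    pd.DataFrame(seg_rows).to_csv(seg_path, index=False)
    pd.DataFrame(pt_rows).to_csv(pt_path, index=False, float_format="%.17g")


def _read_tabular(path: Path) -> SpatialGraph:
    seg_path, pt_path = _tabular_paths(path)
    for p in (seg_path, pt_path):
        if not p.exists():
            raise ParseError(f"tabular dialect: missing {p}")
    segs = pd.read_csv(seg_path)
    pts = pd.read_csv(pt_path)
    graph = SpatialGraph(metadata={"units": "um", "provenance": str(path)})
    node_pos: dict[int, np.ndarray] = {}
    by_seg = dict(tuple(pts.groupby("segment_id")))
    for row in segs.itertuples():
        chunk = by_seg[row.segment_id].sort_values("point_index")
        xyz = chunk[["x_um", "y_um", "z_um"]].to_numpy()
        node_pos.setdefault(int(row.start_node), xyz[0])
        node_pos.setdefault(int(row.end_node), xyz[-1])
    for nid in sorted(node_pos):
        graph.add_node(Node(id=nid, position=node_pos[nid]))
    for row in segs.itertuples():
        chunk = by_seg[row.segment_id].sort_values("point_index")
        comp = row.compartment if isinstance(row.compartment, str) and row.compartment else None
        graph.add_segment(
            Segment(
                id=int(row.segment_id),
                start_node=int(row.start_node),
                end_node=int(row.end_node),
                points=chunk[["x_um", "y_um", "z_um"]].to_numpy(),
                radii=chunk["radius_um"].to_numpy(),
                compartment=comp,
            )
        )
    return graph


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def read_spatial_graph(
    path: str | Path,
    dialect: str = "amira_ascii",
    thickness_is_diameter: bool = False,
) -> SpatialGraph:
    """Read a vessel spatial graph.

    Parameters
    ----------
    path : file path (for ``tabular``, the base path of the two tables).
    dialect : ``amira_ascii`` or ``tabular``.
    thickness_is_diameter : treat the AmiraMesh thickness channel as diameter.
    """
    path = Path(path)
    if dialect == "amira_ascii":
        if not path.exists():
            raise FileNotFoundError(path)
        return _parse_amira(path, thickness_is_diameter)
    if dialect == "tabular":
        return _read_tabular(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_spatial_graph(graph: SpatialGraph, path: str | Path, dialect: str = "amira_ascii") -> None:
    """Write ``graph`` so that :func:`read_spatial_graph` round-trips it."""
    path = Path(path)
    if dialect == "amira_ascii":
        _write_amira(graph, path)
    elif dialect == "tabular":
        _write_tabular(graph, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
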