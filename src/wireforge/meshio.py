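"""Mesh serialization: ASCII PLY, OBJ and a JSON form that keeps labels.

PLY and OBJ carry geometry and faces only — the formats downstream
sequence-design tools (ATHENA/DAEDALUS-style) consume.  The JSON form
additionally round-trips the design labels: preserved flags, the edge
type and the bounding box.  Coordinates are written with six decimals
(nm), so export -> import -> export is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

from .errors import UnsupportedFormatError
from .mesh import (
    BoundingBox,
    DesignState,
    EdgeTypeSpec,
    EDGE_TYPES,
    canonical_face,
    make_edge,
)

_FMT = "{:.6f}"


def _vertex_order(state: DesignState) -> tuple[list[int], dict[int, int]]:
    ids = sorted(state.positions)
    return ids, {vid: i for i, vid in enumerate(ids)}


def export_design(state: DesignState, path, fmt: str | None = None) -> Path:
    """Write a design to PLY, OBJ or JSON (format from extension if omitted)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "ply":
        text = to_ply(state)
    elif fmt == "obj":
        text = to_obj(state)
    elif fmt == "json":
        text = json.dumps(to_dict(state), indent=2) + "\n"
    else:
        raise UnsupportedFormatError(f"unsupported mesh format {fmt!r} (ply/obj/json)")
    path.write_text(text)
    return path


def import_design(
    path,
    fmt: str | None = None,
    box: BoundingBox | None = None,
    edge_type: EdgeTypeSpec | None = None,
) -> DesignState:
    """Read a design back.  PLY/OBJ carry no labels, so a box and edge type
    may be supplied (defaults: tight axis-aligned box, 2HB)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    text = path.read_text()
    if fmt == "ply":
        verts, faces = _parse_ply(text)
    elif fmt == "obj":
        verts, faces = _parse_obj(text)
    elif fmt == "json":
        return from_dict(json.loads(text))
    else:
        raise UnsupportedFormatError(f"unsupported mesh format {fmt!r} (ply/obj/json)")
    return _state_from_geometry(verts, faces, box, edge_type)


def _state_from_geometry(verts, faces, box, edge_type) -> DesignState:
    if box is None:
        xs = [v[0] for v in verts]
        ys = [v[1] for v in verts]
        zs = [v[2] for v in verts]
        box = BoundingBox(
            max(max(xs) - min(xs), 1.0),
            max(max(ys) - min(ys), 1.0),
            max(max(zs) - min(zs), 1.0),
            origin=(min(xs), min(ys), min(zs)),
        )
    edges = set()
    for f in faces:
        for i in range(3):
            edges.add(make_edge(f[i], f[(i + 1) % 3]))
    return DesignState.build(
        positions={i: v for i, v in enumerate(verts)},
        edges=edges,
        faces=faces,
        box=box,
        edge_type=edge_type or EDGE_TYPES["2HB"],
    )


def to_ply(state: DesignState) -> str:
    ids, index = _vertex_order(state)
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(ids)}",
        "property float x",
        "property float y",
        "property float z",
        f"element face {state.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for vid in ids:
        x, y, z = state.positions[vid]
        lines.append(" ".join(_FMT.format(c) for c in (x, y, z)))
    for f in sorted(state.faces):
        lines.append("3 " + " ".join(str(index[v]) for v in f))
    return "\n".join(lines) + "\n"


def _parse_ply(text: str) -> tuple[list, list]:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0] != "ply":
        raise UnsupportedFormatError("not an ASCII PLY file")
    n_vert = n_face = 0
    i = 0
    while lines[i] != "end_header":
        if lines[i].startswith("element vertex"):
            n_vert = int(lines[i].split()[-1])
        elif lines[i].startswith("element face"):
            n_face = int(lines[i].split()[-1])
        i += 1
    i += 1
    verts = [tuple(float(x) for x in lines[i + k].split()[:3]) for k in range(n_vert)]
    i += n_vert
    faces = []
    for k in range(n_face):
        parts = lines[i + k].split()
        if int(parts[0]) != 3:
            raise UnsupportedFormatError("only triangular faces are supported")
        faces.append(canonical_face(tuple(int(x) for x in parts[1:4])))
    return verts, faces


def to_obj(state: DesignState) -> str:
    ids, index = _vertex_order(state)
    lines = []
    for vid in ids:
        x, y, z = state.positions[vid]
        lines.append("v " + " ".join(_FMT.format(c) for c in (x, y, z)))
    for f in sorted(state.faces):
        lines.append("f " + " ".join(str(index[v] + 1) for v in f))
    return "\n".join(lines) + "\n"


def _parse_obj(text: str) -> tuple[list, list]:
    verts, faces = [], []
    for ln in text.splitlines():
        parts = ln.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append(tuple(float(x) for x in parts[1:4]))
        elif parts[0] == "f":
            idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
            if len(idx) != 3:
                raise UnsupportedFormatError("only triangular faces are supported")
            faces.append(canonical_face(tuple(idx)))
    return verts, faces


def to_dict(state: DesignState) -> dict:
    """Label-preserving JSON form of a design state."""
    ids, index = _vertex_order(state)
    return {
        "format": "wireforge-design",
        "version": 1,
        "vertices": [
            {
                "id": vid,
                "position": [float(_FMT.format(c)) for c in state.positions[vid]],
                "preserved": vid in state.preserved_vertices,
            }
            for vid in ids
        ],
        "edges": [
            {"endpoints": list(e), "preserved": e in state.preserved_edges}
            for e in state.sorted_edges()
        ],
        "faces": [list(f) for f in sorted(state.faces)],
        "box": {
            "a": state.box.a,
            "b": state.box.b,
            "c": state.box.c,
            "gamma": state.box.gamma,
            "origin": list(state.box.origin),
        },
        "edge_type": {
            "name": state.edge_type.name,
            "helices_per_edge": state.edge_type.helices_per_edge,
            "bundle_diameter": state.edge_type.bundle_diameter,
            "min_edge_nt": state.edge_type.min_edge_nt,
            "scaffold_passes": state.edge_type.scaffold_passes,
        },
    }


def from_dict(data: dict) -> DesignState:
    if data.get("format") != "wireforge-design":
        raise UnsupportedFormatError("not a wireforge design JSON document")
    box = BoundingBox(
        data["box"]["a"],
        data["box"]["b"],
        data["box"]["c"],
        data["box"]["gamma"],
        tuple(data["box"]["origin"]),
    )
    et = data["edge_type"]
    edge_type = EdgeTypeSpec(
        et["name"], et["helices_per_edge"], et["bundle_diameter"],
        et["min_edge_nt"], et["scaffold_passes"],
    )
    return DesignState.build(
        positions={v["id"]: v["position"] for v in data["vertices"]},
        edges=[e["endpoints"] for e in data["edges"]],
        faces=data["faces"],
        box=box,
        edge_type=edge_type,
        preserved_vertices=[v["id"] for v in data["vertices"] if v["preserved"]],
        preserved_edges=[e["endpoints"] for e in data["edges"] if e["preserved"]],
    )
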