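"""Reading and writing tagged triangle meshes.

Plain PLY and OFF files are handled by :mod:`trimesh`.  For tagged meshes the
package uses an ASCII PLY dialect with two extensions:

* a per-face integer property ``face_tag`` (cell-face label, default 0), and
* an extra element ``edge_tag`` listing cell-edge records as
  ``(v1, v2, dihedral, edge_class)`` with the class encoded as an integer and
  the code-to-name table stored in header comments
  (``comment edge_class <code> <name>``).

This dialect is a minimal standard-conforming PLY extension; generic PLY
readers that ignore unknown elements can still read the geometry.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import trimesh

from .surface import CELL_EDGE, MeshError, TriangulatedSurface


def load_tagged_mesh(path: str | Path, dialect: str | None = None) -> TriangulatedSurface:
    """Load a (possibly tagged) mesh file as a :class:`TriangulatedSurface`.

    Parameters
    ----------
    path : file path
    dialect : {"ply", "off"}, optional
        Defaults to the file extension.

    Raises
    ------
    MeshError
        For non-manifold meshes, non-triangle faces, or unparseable files.
    """
    path = Path(path)
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower()
    if dialect not in ("ply", "off"):
        raise ValueError(f"unknown mesh dialect {dialect!r}")

    if dialect == "ply" and _is_tagged_ply(path):
        return _read_tagged_ply(path)

    mesh = trimesh.load(str(path), file_type=dialect, process=False)
    if not isinstance(mesh, trimesh.Trimesh):
        raise MeshError(f"{path} does not contain a triangle mesh")
    faces = np.asarray(mesh.faces)
    if faces.shape[1] != 3:
        raise MeshError("mesh contains non-triangle faces")
    return TriangulatedSurface(np.asarray(mesh.vertices), faces)


def _is_tagged_ply(path: Path) -> bool:
    try:
        with open(path, "rb") as fh:
            header = fh.read(4096).decode("ascii", errors="replace")
    except OSError:
        return False
    return "face_tag" in header or "element edge_tag" in header


def _read_tagged_ply(path: Path) -> TriangulatedSurface:
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise MeshError(f"{path} is not a PLY file")
        elements: list[tuple[str, int, list[str]]] = []
        class_names: dict[int, str] = {}
        props: list[str] = []
        while True:
            line = fh.readline()
            if not line:
                raise MeshError(f"{path}: unexpected end of PLY header")
            tokens = line.split()
            if not tokens:
                continue
            if tokens[0] == "format":
                if tokens[1] != "ascii":
                    raise MeshError("tagged PLY dialect must be ascii")
            elif tokens[0] == "comment":
                if len(tokens) == 4 and tokens[1] == "edge_class":
                    class_names[int(tokens[2])] = tokens[3]
            elif tokens[0] == "element":
                props = []
                elements.append((tokens[1], int(tokens[2]), props))
            elif tokens[0] == "property":
                props.append(tokens[-1])
            elif tokens[0] == "end_header":
                break

        data: dict[str, list[list[float]]] = {}
        for name, count, _props in elements:
            rows = []
            for _ in range(count):
                rows.append([float(t) for t in fh.readline().split()])
            data[name] = rows

    if "vertex" not in data or "face" not in data:
        raise MeshError(f"{path}: missing vertex or face element")
    vertices = np.array([r[:3] for r in data["vertex"]], dtype=float)

    face_props = next(p for n, c, p in elements if n == "face")
    has_tag = "face_tag" in face_props
    faces, face_tags = [], []
    for row in data["face"]:
        n = int(row[0])
        if n != 3:
            raise MeshError("mesh contains non-triangle faces")
        faces.append([int(v) for v in row[1:4]])
        if has_tag:
            try:
                face_tags.append(int(row[4]))
            except (IndexError, ValueError):
                warnings.warn("unreadable face_tag property; defaulting to 0")
                face_tags.append(0)
    faces = np.array(faces, dtype=np.int64)
    tags = np.array(face_tags, dtype=np.int64) if has_tag else None

    edge_tags = {}
    for row in data.get("edge_tag", []):
        a, b = int(row[0]), int(row[1])
        dihedral = float(row[2])
        cls = class_names.get(int(row[3])) if len(row) > 3 else None
        edge_tags[tuple(sorted((a, b)))] = (cls, dihedral)

    return TriangulatedSurface(vertices, faces, face_tags=tags, edge_tags=edge_tags)


def write_tagged_ply(surface: TriangulatedSurface, path: str | Path) -> None:
    """Write a surface to the tagged ASCII PLY dialect (bit-exact tag round-trip)."""
    path = Path(path)
    cell_edges = surface.cell_edges()
    classes = sorted({r.edge_class for r in cell_edges if r.edge_class is not None})
    class_codes = {name: i + 1 for i, name in enumerate(classes)}

    lines = ["ply", "format ascii 1.0", "comment mtcortex tagged mesh"]
    for name, code in class_codes.items():
        lines.append(f"comment edge_class {code} {name}")
    lines += [
        f"element vertex {len(surface.vertices)}",
        "property double x", "property double y", "property double z",
        f"element face {len(surface.faces)}",
        "property list uchar int vertex_indices",
        "property int face_tag",
        f"element edge_tag {len(cell_edges)}",
        "property int v1", "property int v2",
        "property double dihedral", "property int edge_class",
        "end_header",
    ]
    for v in surface.vertices:
        lines.append(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}")
    for tri, tag in zip(surface.faces, surface.face_tags):
        lines.append(f"3 {int(tri[0])} {int(tri[1])} {int(tri[2])} {int(tag)}")
    for rec in cell_edges:
        code = class_codes.get(rec.edge_class, 0)
        a, b = rec.vertices
        lines.append(f"{a} {b} {float(rec.dihedral)!r} {code}")
    path.write_text("\n".join(lines) + "\n")
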