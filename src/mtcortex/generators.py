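"""Generators for the validation geometries: sphere, cube, rounded cuboid,
and a synthetic lobed ("pavement-like") cell.

All generators return closed, consistently wound
:class:`~mtcortex.surface.TriangulatedSurface` objects with the tags the
simulation scenarios expect:

* ``make_cube`` tags the 12 cube edges as ``cell_edge`` and classifies them as
  *transverse* (the 8 edges bordering the top and bottom faces) or
  *longitudinal* (the 4 vertical side edges).
* ``make_rounded_cuboid`` gives each of the 6 flat face regions a distinct
  ``face_tag`` and tags the shared edges inside the rounded strips as cell
  edges (carrying their local dihedral angles), so that the bending-angle
  edge-catastrophe model acts only on the high-curvature strips.
* ``make_lobed_cell`` is a synthetic stand-in for segmented leaf pavement
  cells: a flattened, semi-2D extrusion of a sinusoidally lobed outline.
"""

from __future__ import annotations

import logging

import numpy as np
import trimesh
from scipy.spatial import ConvexHull

from .surface import TriangulatedSurface

log = logging.getLogger(__name__)

SPHERE_METHODS = ("icosphere", "uv", "random-delaunay", "octasphere")


# ----------------------------------------------------------------------
# Sphere
# ----------------------------------------------------------------------

def make_sphere(radius: float, n_triangles: int = 1000,
                method: str = "icosphere", seed: int = 0) -> TriangulatedSurface:
    """Triangulate a sphere with approximately ``n_triangles`` triangles.

    Four independent constructions are available (``icosphere``, ``uv``,
    ``random-delaunay``, ``octasphere``); all place every vertex exactly at
    distance ``radius`` from the centre.  When the requested triangle count is
    not achievable for the method, the nearest achievable count is used and
    logged.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_triangles < 4:
        raise ValueError("n_triangles must be at least 4")
    if method == "icosphere":
        # achievable counts: 20 * 4^k
        k = max(0, round(np.log(n_triangles / 20.0) / np.log(4.0)))
        mesh = trimesh.creation.icosphere(subdivisions=int(k), radius=1.0)
        verts, faces = np.asarray(mesh.vertices), np.asarray(mesh.faces)
    elif method == "uv":
        # uv sphere with m rings x n sectors has ~2*m*n triangles
        m = max(3, int(round(np.sqrt(n_triangles / 4.0))))
        mesh = trimesh.creation.uv_sphere(radius=1.0, count=(m, 2 * m))
        verts, faces = np.asarray(mesh.vertices), np.asarray(mesh.faces)
    elif method == "random-delaunay":
        # convex hull of n random points on the sphere has 2n - 4 triangles
        n_pts = max(4, (n_triangles + 4) // 2)
        rng = np.random.default_rng(seed)
        verts = rng.standard_normal((n_pts, 3))
        verts /= np.linalg.norm(verts, axis=1, keepdims=True)
        hull = ConvexHull(verts)
        faces = hull.simplices
    elif method == "octasphere":
        # achievable counts: 8 * 4^k
        k = max(0, round(np.log(n_triangles / 8.0) / np.log(4.0)))
        verts = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                          [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
        faces = np.array([[0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
                          [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5]])
        for _ in range(int(k)):
            verts, faces = trimesh.remesh.subdivide(verts, faces)
        verts = np.asarray(verts, dtype=float)
    else:
        raise ValueError(f"unknown sphere method {method!r}; "
                         f"choose from {SPHERE_METHODS}")

    verts = verts / np.linalg.norm(verts, axis=1, keepdims=True) * radius
    if len(faces) != n_triangles:
        log.info("sphere method %s: using %d triangles (requested %d)",
                 method, len(faces), n_triangles)
    return TriangulatedSurface(verts, faces, metadata={
        "shape": "sphere", "radius": radius, "method": method})


# ----------------------------------------------------------------------
# Cube
# ----------------------------------------------------------------------

def make_cube(side: float,
              edge_probabilities: tuple[float, float] | None = None
              ) -> TriangulatedSurface:
    """Cube of the given side, each face split into 4 isosceles triangles.

    The 24-triangle mesh has a centre vertex on every face; the face diagonals
    are untagged.  The 12 cube edges are tagged as cell edges with dihedral
    pi/2: the 8 edges bordering the top and bottom faces are classified
    ``transverse``, the 4 vertical side edges ``longitudinal``.  The z axis is
    the (virtual) organ axis, perpendicular to the top and bottom faces.

    ``edge_probabilities`` = (P_transverse, P_longitudinal), when given, is
    stored in the metadata as the default constant edge-catastrophe
    probabilities for the two classes.
    """
    if side <= 0:
        raise ValueError("side must be positive")
    h = side / 2.0
    corners = np.array([[sx, sy, sz] for sx in (-h, h)
                        for sy in (-h, h) for sz in (-h, h)], dtype=float)
    # face centres: -x, +x, -y, +y, -z, +z
    centers = np.array([[-h, 0, 0], [h, 0, 0], [0, -h, 0],
                        [0, h, 0], [0, 0, -h], [0, 0, h]], dtype=float)
    verts = np.vstack([corners, centers])

    def cidx(sx, sy, sz):
        return (sx > 0) * 4 + (sy > 0) * 2 + (sz > 0)

    faces = []
    face_tags = []
    # each cube face: 4 corner loop + its centre vertex
    face_defs = [
        ([(-1, -1, -1), (-1, -1, 1), (-1, 1, 1), (-1, 1, -1)], 8 + 0),   # -x
        ([(1, -1, -1), (1, 1, -1), (1, 1, 1), (1, -1, 1)], 8 + 1),       # +x
        ([(-1, -1, -1), (1, -1, -1), (1, -1, 1), (-1, -1, 1)], 8 + 2),   # -y
        ([(-1, 1, -1), (-1, 1, 1), (1, 1, 1), (1, 1, -1)], 8 + 3),       # +y
        ([(-1, -1, -1), (-1, 1, -1), (1, 1, -1), (1, -1, -1)], 8 + 4),   # -z
        ([(-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1)], 8 + 5),       # +z
    ]
    for tag, (loop, center) in enumerate(face_defs, start=1):
        ids = [cidx(*s) for s in loop]
        for i in range(4):
            faces.append([ids[i], ids[(i + 1) % 4], center])
            face_tags.append(tag)
    faces = np.array(faces, dtype=np.int64)

    # the 12 cube edges: corner pairs differing in exactly one coordinate
    edge_tags = {}
    for i in range(8):
        for j in range(i + 1, 8):
            diff = corners[i] != corners[j]
            if diff.sum() == 1:
                vertical = bool(diff[2])
                cls = "longitudinal" if vertical else "transverse"
                edge_tags[(i, j)] = (cls, np.pi / 2.0)

    metadata = {"shape": "cube", "side": side, "axis": [0.0, 0.0, 1.0]}
    if edge_probabilities is not None:
        metadata["edge_class_probabilities"] = {
            "transverse": float(edge_probabilities[0]),
            "longitudinal": float(edge_probabilities[1]),
        }
    return TriangulatedSurface(verts, faces, face_tags=np.array(face_tags),
                               edge_tags=edge_tags, metadata=metadata)


# ----------------------------------------------------------------------
# Rounded cuboid
# ----------------------------------------------------------------------

def _box_sdf(p: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Signed distance from points ``p`` to a box with half-extents ``h``."""
    q = np.abs(p) - h
    outside = np.linalg.norm(np.maximum(q, 0.0), axis=-1)
    inside = np.minimum(np.max(q, axis=-1), 0.0)
    return outside + inside


def make_rounded_cuboid(a: float, b: float, c: float, rounding: float = 0.75,
                        n_triangles: int = 1000) -> TriangulatedSurface:
    """Rectangular parallelepiped a x b x c (um) with rounded edges.

    Constructed as the offset surface at distance ``rounding`` of the inner
    box with half extents ((a, b, c)/2 - rounding), sampled along icosphere
    directions by bisection on the signed distance function.  The 6 flat face
    regions carry distinct face tags 1..6; triangle edges inside the rounded
    strips are tagged as cell edges with their local dihedral angles.  The
    box axes p_a = x, p_b = y, p_c = z are emitted as metadata together with
    the cross-section circumferences.
    """
    if not (a >= b >= c > 0):
        raise ValueError("dimensions must satisfy a >= b >= c > 0")
    if not (0 < rounding < c / 2):
        raise ValueError("rounding must lie in (0, c/2)")

    h = np.array([a, b, c]) / 2.0 - rounding
    sphere = make_sphere(1.0, n_triangles, method="icosphere")
    dirs = sphere.vertices / np.linalg.norm(sphere.vertices, axis=1, keepdims=True)

    # bisection on t: sdf(t * dir) = rounding   (star-shaped surface)
    lo = np.zeros(len(dirs))
    hi = np.full(len(dirs), float(np.linalg.norm(h) + 2 * rounding))
    for _ in range(70):
        mid = 0.5 * (lo + hi)
        f = _box_sdf(mid[:, None] * dirs, h) - rounding
        lo = np.where(f < 0, mid, lo)
        hi = np.where(f < 0, hi, mid)
    verts = (0.5 * (lo + hi))[:, None] * dirs
    faces = sphere.faces

    # tag triangles whose three vertices lie on the same flat face plane
    face_tags = np.zeros(len(faces), dtype=np.int64)
    tol = 1e-6 * max(a, b, c)
    full = np.array([a, b, c]) / 2.0
    on_plane = []  # (axis, sign) planes -> boolean per vertex
    planes = []
    for axis in range(3):
        for sign in (-1.0, 1.0):
            planes.append((axis, sign))
            on_plane.append(np.abs(verts[:, axis] - sign * full[axis]) < tol)
    for t, tri in enumerate(faces):
        for k, mask in enumerate(on_plane):
            if mask[tri].all():
                face_tags[t] = k + 1
                break

    edge_tags = {}
    surf0 = TriangulatedSurface(verts, faces, face_tags=face_tags)
    for rec in surf0.edges.values():
        f, g = rec.faces
        if face_tags[f] == 0 or face_tags[g] == 0 or face_tags[f] != face_tags[g]:
            if rec.dihedral > 1e-9:
                edge_tags[rec.vertices] = ("rounded", rec.dihedral)

    metadata = {
        "shape": "rounded_cuboid", "a": a, "b": b, "c": c, "rounding": rounding,
        "axes": {"p_a": [1.0, 0.0, 0.0], "p_b": [0.0, 1.0, 0.0],
                 "p_c": [0.0, 0.0, 1.0]},
        # cross-section circumferences perpendicular to each axis; both the
        # raw perimeter 2(b+c) and the half-perimeter (b+c) are reported, as
        # only their ordering C_a < C_b < C_c enters any analysis
        "circumference": {"C_a": 2 * (b + c), "C_b": 2 * (a + c), "C_c": 2 * (a + b)},
        "half_circumference": {"C_a": b + c, "C_b": a + c, "C_c": a + b},
    }
    return TriangulatedSurface(np.asarray(surf0.vertices), np.asarray(surf0.faces),
                               face_tags=face_tags, edge_tags=edge_tags,
                               metadata=metadata)


# ----------------------------------------------------------------------
# Lobed cell (synthetic pavement-cell stand-in)
# ----------------------------------------------------------------------

def make_lobed_cell(n_lobes: int, lobe_depth: float, base_radius: float,
                    n_triangles: int = 600, seed: int = 0,
                    thickness: float | None = None,
                    target_area: float | None = None) -> TriangulatedSurface:
    """Synthetic flattened cell with a sinusoidally lobed outline.

    A semi-2D closed shape: the outline r(phi) = base_radius +
    lobe_depth * sin(n_lobes * phi) is extruded to a small thickness, giving a
    closed manifold with smooth lobes and necks.  This is a synthetic
    stand-in for segmented leaf pavement cell meshes.  ``target_area``
    rescales the result to the given total surface area.
    """
    if n_lobes < 0:
        raise ValueError("n_lobes must be non-negative")
    if n_lobes >= 2 and lobe_depth >= base_radius:
        raise ValueError("lobe_depth must be smaller than base_radius "
                         "(self-intersecting outline)")
    if thickness is None:
        thickness = 0.3 * base_radius

    n_outline = max(24, 12 * max(n_lobes, 1), int(np.sqrt(n_triangles) * 3))
    phi = np.linspace(0.0, 2 * np.pi, n_outline, endpoint=False)
    r = base_radius + (lobe_depth * np.sin(n_lobes * phi) if n_lobes >= 2 else 0.0)
    if np.any(r <= 0):
        raise ValueError("self-intersecting outline: radius must stay positive")
    outline = np.column_stack([r * np.cos(phi), r * np.sin(phi)])

    import shapely.geometry as sg
    if not sg.Polygon(outline).is_valid:
        raise ValueError("self-intersecting outline")

    # the polar outline is star-shaped about the origin, so both caps can be
    # fan-triangulated from a centre vertex; the side wall is a quad strip
    h = thickness / 2.0
    n = n_outline
    top = np.column_stack([outline, np.full(n, h)])
    bot = np.column_stack([outline, np.full(n, -h)])
    centers = np.array([[0.0, 0.0, h], [0.0, 0.0, -h]])
    verts = np.vstack([top, bot, centers])
    c_top, c_bot = 2 * n, 2 * n + 1
    faces = []
    for i in range(n):
        j = (i + 1) % n
        faces.append([c_top, i, j])                    # top cap (+z)
        faces.append([c_bot, n + j, n + i])            # bottom cap (-z)
        faces.append([i, n + i, j])                    # side wall
        faces.append([j, n + i, n + j])
    surf = TriangulatedSurface(
        verts, np.asarray(faces),
        metadata={"shape": "lobed_cell", "n_lobes": n_lobes,
                  "lobe_depth": lobe_depth, "base_radius": base_radius,
                  "synthetic": True},
    )
    if target_area is not None:
        surf = surf.rescaled_to_area(target_area)
    return surf
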