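"""Triangulated cell surfaces and their flattened (2D chart) representation.

A plant cell cortex is modelled as a closed triangulated 2-manifold embedded in
3D.  Microtubule dynamics is simulated inside per-triangle 2D charts: each
triangle is mapped isometrically into the x-y plane by a rotation (stored as a
quaternion) plus a z-translation.  Charts are positioned independently of each
other; all inter-triangle geometry is carried by edge transition maps, which
translate a point on the shared edge between the two chart images and rotate
directions by the signed angle between the two edge images.  A straight line
continued through such a transition is the geodesic (locally straightest path)
on the polyhedral surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

#: geometric tolerance (micrometres) used throughout the package
GEOM_TOL = 1e-9

#: triangles with area below this (um^2) are rejected as degenerate
DEGENERATE_AREA = 1e-12

CELL_EDGE = "cell_edge"


class MeshError(ValueError):
    """Raised for meshes that violate the closed-manifold requirements."""


@dataclass
class EdgeRecord:
    """Shared-edge annotation between two adjacent triangles."""

    vertices: tuple[int, int]          # global vertex ids, sorted
    faces: tuple[int, int]
    tag: str = "none"                  # "none" or "cell_edge"
    edge_class: str | None = None      # e.g. "transverse" / "longitudinal"
    dihedral: float = 0.0              # radians, in [0, pi); 0 for coplanar


class TriangulatedSurface:
    """A closed, consistently wound triangle mesh with face and edge tags.

    Parameters
    ----------
    vertices : (V, 3) float array, micrometres
    faces : (F, 3) int array
        Vertex index triples.  Windings are repaired to a consistent outward
        orientation on construction.
    face_tags : (F,) int array, optional
        Integer cell-face tag per triangle (default 0).
    edge_tags : mapping {(v_i, v_j): (edge_class, dihedral or None)}, optional
        Cell-edge annotations keyed by the sorted vertex pair of a shared
        edge.  When the stored dihedral is None it is computed from the mesh
        geometry.
    metadata : dict, optional
        Free-form metadata (e.g. reference axes of a generated shape).
    """

    def __init__(
        self,
        vertices: np.ndarray,
        faces: np.ndarray,
        face_tags: np.ndarray | None = None,
        edge_tags: Mapping[tuple[int, int], tuple[str | None, float | None]] | None = None,
        metadata: dict | None = None,
    ):
        vertices = np.asarray(vertices, dtype=float)
        faces = np.asarray(faces, dtype=np.int64)
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise MeshError("vertices must be an (V, 3) array")
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise MeshError("faces must be an (F, 3) array of vertex triples")

        mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
        self._validate_manifold(mesh)
        # Repair windings to a globally consistent, outward orientation.
        trimesh.repair.fix_normals(mesh)
        if mesh.is_watertight and mesh.volume < 0:
            mesh.invert()

        self.vertices = np.asarray(mesh.vertices, dtype=float)
        self.faces = np.asarray(mesh.faces, dtype=np.int64)
        self.face_tags = (
            np.zeros(len(self.faces), dtype=np.int64)
            if face_tags is None
            else np.asarray(face_tags, dtype=np.int64).copy()
        )
        if len(self.face_tags) != len(self.faces):
            raise MeshError("face_tags length must equal number of faces")
        self.metadata = dict(metadata or {})

        self.normals = np.asarray(mesh.face_normals, dtype=float)
        self.areas = np.asarray(mesh.area_faces, dtype=float)
        if np.any(self.areas < DEGENERATE_AREA):
            bad = int(np.argmin(self.areas))
            raise MeshError(f"degenerate (zero-area) triangle {bad}")
        self.total_area = float(self.areas.sum())

        self._build_edges(edge_tags or {})

    # ------------------------------------------------------------------
    def _validate_manifold(self, mesh: trimesh.Trimesh) -> None:
        edges = mesh.edges_sorted
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        bad = uniq[counts != 2]
        if len(bad):
            a, b = (int(v) for v in bad[0])
            raise MeshError(
                f"non-manifold/boundary edge ({a}, {b}): shared by "
                f"{int(counts[counts != 2][0])} triangles, expected 2"
            )

    def _build_edges(self, edge_tags) -> None:
        """Build the shared-edge table: {(a, b) sorted: EdgeRecord}."""
        edge_faces: dict[tuple[int, int], list[int]] = {}
        for f, tri in enumerate(self.faces):
            for j in range(3):
                key = tuple(sorted((int(tri[j]), int(tri[(j + 1) % 3]))))
                edge_faces.setdefault(key, []).append(f)
        self.edges: dict[tuple[int, int], EdgeRecord] = {}
        for key, fs in edge_faces.items():
            f, g = fs
            n1, n2 = self.normals[f], self.normals[g]
            cosang = float(np.clip(np.dot(n1, n2), -1.0, 1.0))
            dihedral = float(np.arccos(cosang))
            tag, edge_class = "none", None
            if key in edge_tags:
                edge_class, stored = edge_tags[key]
                tag = CELL_EDGE
                if stored is not None:
                    dihedral = float(stored)
            self.edges[key] = EdgeRecord(
                vertices=key, faces=(f, g), tag=tag,
                edge_class=edge_class, dihedral=dihedral,
            )

    # ------------------------------------------------------------------
    def tag_edge(self, a: int, b: int, edge_class: str | None = None,
                 dihedral: float | None = None) -> None:
        """Mark the shared edge (a, b) as a cell edge."""
        key = tuple(sorted((int(a), int(b))))
        rec = self.edges[key]
        rec.tag = CELL_EDGE
        rec.edge_class = edge_class
        if dihedral is not None:
            rec.dihedral = float(dihedral)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def euler_characteristic(self) -> int:
        return len(self.vertices) - len(self.edges) + len(self.faces)

    def cell_edges(self) -> list[EdgeRecord]:
        return [r for r in self.edges.values() if r.tag == CELL_EDGE]

    def rescaled_to_area(self, target_area: float) -> "TriangulatedSurface":
        """Return a copy uniformly rescaled to the given total area (um^2)."""
        s = float(np.sqrt(target_area / self.total_area))
        edge_tags = {
            r.vertices: (r.edge_class, r.dihedral)
            for r in self.edges.values() if r.tag == CELL_EDGE
        }
        return TriangulatedSurface(
            self.vertices * s, self.faces, self.face_tags,
            edge_tags=edge_tags, metadata=dict(self.metadata),
        )


# ----------------------------------------------------------------------
# Flattened charts
# ----------------------------------------------------------------------

@dataclass
class FlattenedChart:
    """Isometric image of one triangle in the x-y plane.

    ``rotation`` maps 3D points into chart space (x, y, z0); the inverse
    rotation lifts chart points back onto the surface.  The 2D winding of
    ``verts2`` is positive (counterclockwise) for an outward-facing triangle.
    """

    face: int
    verts2: np.ndarray          # (3, 2) chart coordinates of the vertices
    quat: np.ndarray            # unit quaternion (x, y, z, w) of the rotation
    z0: float                   # common z of the rotated triangle

    def to_chart(self, points3: np.ndarray) -> np.ndarray:
        rot = Rotation.from_quat(self.quat)
        return rot.apply(np.atleast_2d(points3))[:, :2]

    def to_surface(self, points2: np.ndarray) -> np.ndarray:
        points2 = np.atleast_2d(points2)
        p3 = np.column_stack([points2, np.full(len(points2), self.z0)])
        rot = Rotation.from_quat(self.quat)
        return rot.inv().apply(p3)

    def contains(self, point2: np.ndarray, tol: float = GEOM_TOL) -> bool:
        a, b, c = self.verts2
        v0, v1 = b - a, c - a
        den = v0[0] * v1[1] - v0[1] * v1[0]
        p = np.asarray(point2, dtype=float) - a
        u = (p[0] * v1[1] - p[1] * v1[0]) / den
        v = (v0[0] * p[1] - v0[1] * p[0]) / den
        scale = max(1.0, abs(den)) ** 0.5
        t = tol / scale + 1e-12
        return u >= -t and v >= -t and u + v <= 1 + t


def _rotation_to_plane(normal: np.ndarray) -> Rotation:
    """Rotation taking ``normal`` to +z (identity when already +z)."""
    n = normal / np.linalg.norm(normal)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(np.dot(n, z), -1.0, 1.0))
    if c > 1.0 - 1e-14:
        return Rotation.identity()
    if c < -1.0 + 1e-14:
        return Rotation.from_rotvec([np.pi, 0.0, 0.0])
    axis = np.cross(n, z)
    axis /= np.linalg.norm(axis)
    return Rotation.from_rotvec(axis * np.arccos(c))


def flatten(surface: TriangulatedSurface) -> list[FlattenedChart]:
    """Build one isometric 2D chart per triangle.

    Charts are placed independently (they need not tile the plane); only the
    transition maps relate neighbouring charts.  The rotation is chosen so the
    outward normal maps to +z, which makes every chart's 2D winding positive
    and collision angles unambiguous.
    """
    charts = []
    for f in range(surface.n_faces):
        rot = _rotation_to_plane(surface.normals[f])
        tri3 = surface.vertices[surface.faces[f]]
        rotated = rot.apply(tri3)
        z0 = float(rotated[:, 2].mean())
        verts2 = rotated[:, :2].copy()
        # positive signed area guaranteed by outward normal -> +z
        a, b, c = verts2
        signed = 0.5 * ((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))
        if signed <= 0:
            raise MeshError(f"chart winding not positive for triangle {f}")
        charts.append(FlattenedChart(face=f, verts2=verts2,
                                     quat=rot.as_quat(), z0=z0))
    return charts


# ----------------------------------------------------------------------
# Transition maps and connectivity
# ----------------------------------------------------------------------

@dataclass
class TransitionMap:
    """Rigid map between the chart images of two adjacent triangles.

    Applying the map to a point on the source chart's image of the shared
    edge yields the same point (same barycentric position) on the target
    chart's image.  Directions are rotated by the signed angle ``theta``;
    continuing a ray straight through the transition realizes the geodesic
    (equal angles with the shared edge on both sides).
    """

    source: int
    target: int
    shared_edge: tuple[int, int]
    theta: float                 # signed rotation angle theta_R, radians
    anchor_src: np.ndarray       # shared-edge endpoint in the source chart
    anchor_dst: np.ndarray       # the corresponding endpoint in the target chart

    def apply_point(self, p: np.ndarray) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        d = np.asarray(p, dtype=float) - self.anchor_src
        return self.anchor_dst + np.array([c * d[0] - s * d[1],
                                           s * d[0] + c * d[1]])

    def apply_direction(self, d: np.ndarray) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        out = np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])
        return out / np.linalg.norm(out)


def _transition(charts: Sequence[FlattenedChart], surface: TriangulatedSurface,
                f: int, g: int) -> TransitionMap:
    """Transition map from face ``f`` to adjacent face ``g``."""
    shared = set(surface.faces[f]) & set(surface.faces[g])
    if len(shared) != 2:
        raise ValueError(f"faces {f} and {g} are not adjacent")
    a, b = sorted(int(v) for v in shared)

    def chart_point(face: int, vertex: int) -> np.ndarray:
        idx = int(np.where(surface.faces[face] == vertex)[0][0])
        return charts[face].verts2[idx]

    af, bf = chart_point(f, a), chart_point(f, b)
    ag, bg = chart_point(g, a), chart_point(g, b)
    u = bf - af
    v = bg - ag
    theta = float(np.arctan2(u[0] * v[1] - u[1] * v[0],
                             u[0] * v[0] + u[1] * v[1]))
    return TransitionMap(source=f, target=g, shared_edge=(a, b),
                         theta=theta, anchor_src=af.copy(), anchor_dst=ag.copy())


class ConnectivityGraph:
    """Adjacency of triangles via shared edges, with transition maps.

    Wraps a :class:`networkx.Graph` whose nodes are triangle ids; every edge
    carries the :class:`EdgeRecord` of the shared mesh edge.  Transition maps
    for both directions are precomputed.
    """

    def __init__(self, surface: TriangulatedSurface,
                 charts: Sequence[FlattenedChart] | None = None):
        self.surface = surface
        self.charts = list(charts) if charts is not None else flatten(surface)
        self.graph = nx.Graph()
        self.graph.add_nodes_from(range(surface.n_faces))
        self._transitions: dict[tuple[int, int], TransitionMap] = {}
        for rec in surface.edges.values():
            f, g = rec.faces
            self.graph.add_edge(f, g, record=rec)
            self._transitions[(f, g)] = _transition(self.charts, surface, f, g)
            self._transitions[(g, f)] = _transition(self.charts, surface, g, f)

    def neighbors(self, face: int) -> list[int]:
        return list(self.graph.neighbors(face))

    def edge_record(self, f: int, g: int) -> EdgeRecord:
        return self.graph.edges[f, g]["record"]

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)


def build_connectivity(surface: TriangulatedSurface) -> ConnectivityGraph:
    """Build the triangle connectivity graph with per-edge transition maps."""
    return ConnectivityGraph(surface)


def transition_map(graph: ConnectivityGraph, source: int, target: int) -> TransitionMap:
    """Return the transition map for an ordered pair of adjacent triangles."""
    key = (int(source), int(target))
    if key not in graph._transitions:
        raise ValueError(f"faces {source} and {target} are not adjacent")
    return graph._transitions[key]


def lift_to_3d(
    charts: Sequence[FlattenedChart],
    segments: Iterable[Sequence[tuple[int, np.ndarray, np.ndarray]]],
    tol: float = 1e-6,
) -> list[np.ndarray]:
    """Lift chains of per-triangle 2D segments back onto the 3D surface.

    Parameters
    ----------
    segments : iterable of chains
        Each chain is a sequence of ``(face, start2, end2)`` tuples describing
        one microtubule from minus end to plus end.  Consecutive segments must
        meet at a shared edge; their lifted 3D junction points coincide.

    Returns
    -------
    list of (N, 3) arrays, one polyline per chain.
    """
    polylines = []
    for chain in segments:
        pts3 = []
        prev_end = None
        for face, p0, p1 in chain:
            chart = charts[face]
            for p in (p0, p1):
                if not chart.contains(p, tol=tol):
                    raise ValueError(
                        f"segment point {tuple(p)} lies outside chart of "
                        f"triangle {face} beyond tolerance"
                    )
            a3, b3 = chart.to_surface(np.array([p0, p1]))
            if prev_end is None:
                pts3.append(a3)
            else:
                if np.linalg.norm(prev_end - a3) > tol:
                    raise ValueError(
                        f"3D junction mismatch at triangle {face}: "
                        f"{np.linalg.norm(prev_end - a3):.3e} um"
                    )
                # keep a single junction point
            pts3.append(b3)
            prev_end = b3
        polylines.append(np.asarray(pts3))
    return polylines
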