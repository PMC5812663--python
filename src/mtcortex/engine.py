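"""Event-driven stochastic simulation of cortical microtubule dynamics.

The simulator advances a population of microtubules (MTs) on the flattened
charts of a triangulated surface, event by event:

* *stochastic* events (nucleation, spontaneous catastrophe, rescue) are drawn
  from exponential waiting times at the current total rate; by memorylessness
  the pending draw is refreshed after every state change;
* *deterministic* events (collisions, edge crossings, segment exhaustion,
  disappearance, measurements) are predicted exactly from the piecewise-linear
  motion of the tips and kept in priority queues.

Growing plus-ends all share the same, possibly time-varying, effective growth
speed (finite tubulin pool), so tip advancement is bookkept against a common
growth-distance coordinate ``W(t) = integral v_plus_eff dt``.  Events tied to
tip growth are queued in ``W``; all other events are queued in real time.
This keeps every scheduled event exact even when the effective growth speed
changes, at O(1) cost per speed change.

Collision candidates are scheduled where the tip's ray intersects the
trajectory lines of segments resident in the same triangle and re-validated
against the obstacle's occupied extent when they come due, so no false
collisions occur and none are missed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from heapq import heappop, heappush

import numpy as np
import pandas as pd

from .order import OrderResult, order_tensor
from .params import SimulationParameters
from .surface import CELL_EDGE, GEOM_TOL, TriangulatedSurface, _rotation_to_plane

_INF = math.inf
_STOL = 1e-9          # arc-length tolerance along a trajectory (um)
_SCAN_HORIZON = 2.0   # lookahead (um) for collision-candidate scans
_LTOL = 1e-9          # length tolerance for disappearance (um)


# ----------------------------------------------------------------------
# Precomputed geometry tables
# ----------------------------------------------------------------------

class _EdgeGeom:
    __slots__ = ("neighbor", "cos_t", "sin_t", "ax", "ay", "bx", "by",
                 "e0x", "e0y", "e1x", "e1y", "elen", "tag", "edge_class",
                 "dihedral", "p_const")

    def __init__(self):
        self.p_const = 0.0


class _FaceGeom:
    __slots__ = ("verts2", "edges", "area", "tag", "rc",
                 "ex3", "ey3", "ez3", "z0")


def _build_geometry(surface: TriangulatedSurface,
                    params: SimulationParameters) -> list[_FaceGeom]:
    """Flatten every triangle and precompute directed edge transitions."""
    # constant edge-catastrophe probabilities per class (mesh defaults,
    # overridden by the parameter set)
    probs = dict(surface.metadata.get("edge_class_probabilities", {}))
    probs.update(params.edge_model.class_probabilities)

    faces = surface.faces
    n = surface.n_faces
    charts2 = []
    geos: list[_FaceGeom] = []
    for f in range(n):
        rot = _rotation_to_plane(surface.normals[f])
        mat = rot.as_matrix()
        tri3 = surface.vertices[faces[f]]
        rotated = tri3 @ mat.T
        g = _FaceGeom()
        g.verts2 = tuple((float(v[0]), float(v[1])) for v in rotated)
        g.z0 = float(rotated[:, 2].mean())
        g.ex3 = tuple(float(x) for x in mat[0])
        g.ey3 = tuple(float(x) for x in mat[1])
        g.ez3 = tuple(float(x) for x in mat[2])
        g.area = float(surface.areas[f])
        g.tag = int(surface.face_tags[f])
        g.rc = float(params.rc_face_overrides.get(g.tag, params.r_c))
        charts2.append(rotated[:, :2])
        geos.append(g)

    # map (sorted vertex pair) -> record
    for f in range(n):
        g = geos[f]
        tri = faces[f]
        edges = []
        for j in range(3):
            a, b = int(tri[j]), int(tri[(j + 1) % 3])
            key = (a, b) if a < b else (b, a)
            rec = surface.edges[key]
            other = rec.faces[0] if rec.faces[1] == f else rec.faces[1]
            eg = _EdgeGeom()
            eg.neighbor = other
            eg.tag = rec.tag == CELL_EDGE
            eg.edge_class = rec.edge_class
            eg.dihedral = rec.dihedral
            if eg.tag and rec.edge_class in probs:
                eg.p_const = float(probs[rec.edge_class])
            # chart coordinates of the shared edge in both charts, anchored
            # at the lower-id shared vertex
            lo = key[0]
            i_f = int(np.where(tri == lo)[0][0])
            i_g = int(np.where(faces[other] == lo)[0][0])
            hi = key[1]
            k_f = int(np.where(tri == hi)[0][0])
            k_g = int(np.where(faces[other] == hi)[0][0])
            af = charts2[f][i_f]
            bf = charts2[f][k_f]
            ag = charts2[other][i_g]
            bg = charts2[other][k_g]
            u = bf - af
            v = bg - ag
            theta = math.atan2(u[0] * v[1] - u[1] * v[0],
                               u[0] * v[0] + u[1] * v[1])
            eg.cos_t = math.cos(theta)
            eg.sin_t = math.sin(theta)
            eg.ax, eg.ay = float(af[0]), float(af[1])
            eg.bx, eg.by = float(ag[0]), float(ag[1])
            # edge endpoints in this chart, in winding order (vertex j -> j+1)
            p0 = charts2[f][j]
            p1 = charts2[f][(j + 1) % 3]
            eg.e0x, eg.e0y = float(p0[0]), float(p0[1])
            eg.e1x, eg.e1y = float(p1[0]), float(p1[1])
            eg.elen = math.hypot(p1[0] - p0[0], p1[1] - p0[1])
            edges.append(eg)
        g.edges = tuple(edges)
    return geos


# ----------------------------------------------------------------------
# Dynamic state
# ----------------------------------------------------------------------

class _Seg:
    """One straight MT segment inside a single triangle chart."""
    __slots__ = ("face", "px", "py", "ux", "uy", "L", "owner", "alive", "slot")

    def __init__(self, face, px, py, ux, uy, owner):
        self.face = face
        self.px = px
        self.py = py
        self.ux = ux
        self.uy = uy
        self.L = 0.0
        self.owner = owner
        self.alive = True
        self.slot = -1


class _MT:
    """One microtubule: a chain of segments plus lazy tip/minus bookkeeping.

    For a growing tip the arc-length position of the plus end along its
    current (last) segment is S(t) = tip_off + W(t); for a shrinking tip
    S(t) = tip_off - v_minus * t.  The minus-end offset into the oldest
    segment is m(t) = m_off + v_tm * t.  ``base`` is the frozen total length
    of all non-tip segments.
    """
    __slots__ = ("id", "segs", "state", "tip_off", "m_off", "base",
                 "rc", "epoch", "alive", "s_exit", "exit_edge", "exit_pt",
                 "horizon_s")

    def __init__(self, mt_id):
        self.id = mt_id
        self.segs = []
        self.state = "g"
        self.tip_off = 0.0
        self.m_off = 0.0
        self.base = 0.0
        self.rc = 0.0
        self.epoch = 0
        self.alive = True
        self.s_exit = _INF
        self.exit_edge = -1
        self.exit_pt = (0.0, 0.0)
        self.horizon_s = _INF


class _FaceRegistry:
    """Segments resident in one triangle, with parallel numpy slot arrays
    so collision-candidate prediction is a single vectorized pass.

    ``LA[slot]`` is +inf while the segment is its owner's growing frontier
    (its occupied extent can still increase) and is set to the frozen length
    once a newer segment exists; candidates beyond that extent can then be
    pruned at prediction time.  Occupancy is always re-checked at pop time.
    """
    __slots__ = ("segs", "px", "py", "ux", "uy", "LA", "n")

    def __init__(self):
        cap = 8
        self.segs: list = []
        self.px = np.empty(cap)
        self.py = np.empty(cap)
        self.ux = np.empty(cap)
        self.uy = np.empty(cap)
        self.LA = np.empty(cap)
        self.n = 0

    def add(self, seg) -> None:
        i = self.n
        if i == len(self.px):
            for name in ("px", "py", "ux", "uy", "LA"):
                arr = getattr(self, name)
                new = np.empty(2 * len(arr))
                new[:len(arr)] = arr
                setattr(self, name, new)
        self.segs.append(seg)
        seg.slot = i
        self.px[i] = seg.px
        self.py[i] = seg.py
        self.ux[i] = seg.ux
        self.uy[i] = seg.uy
        self.LA[i] = _INF
        self.n = i + 1

    def remove(self, seg) -> None:
        i = seg.slot
        last = self.segs.pop()
        self.n -= 1
        if last is not seg:
            self.segs[i] = last
            last.slot = i
            j = self.n
            self.px[i] = self.px[j]
            self.py[i] = self.py[j]
            self.ux[i] = self.ux[j]
            self.uy[i] = self.uy[j]
            self.LA[i] = self.LA[j]
        seg.slot = -1

    def freeze(self, seg, length: float) -> None:
        if seg.slot >= 0:
            self.LA[seg.slot] = length

    def __iter__(self):
        return iter(self.segs)

    def __len__(self):
        return self.n


class _IndexedSet:
    """Set with O(1) add/remove and O(1) uniform random choice."""
    __slots__ = ("items", "pos")

    def __init__(self):
        self.items = []
        self.pos = {}

    def add(self, x):
        if x in self.pos:
            return
        self.pos[x] = len(self.items)
        self.items.append(x)

    def remove(self, x):
        i = self.pos.pop(x)
        last = self.items.pop()
        if i < len(self.items):
            self.items[i] = last
            self.pos[last] = i

    def __len__(self):
        return len(self.items)

    def __contains__(self, x):
        return x in self.pos


class _RateGroups:
    """Growing MTs grouped by their per-face catastrophe rate."""
    __slots__ = ("groups", "total")

    def __init__(self):
        self.groups: dict[float, _IndexedSet] = {}
        self.total = 0.0

    def add(self, mt, rate):
        self.groups.setdefault(rate, _IndexedSet()).add(mt)
        self.total += rate

    def remove(self, mt, rate):
        self.groups[rate].remove(mt)
        self.total -= rate

    def sample(self, u):
        """Pick an MT with probability proportional to its rate; u in [0, total)."""
        acc = 0.0
        for rate, s in self.groups.items():
            w = rate * len(s)
            if u < acc + w:
                idx = int((u - acc) / rate) if rate > 0 else 0
                return s.items[min(idx, len(s) - 1)]
            acc += w
        # numerical edge: return the last non-empty group member
        for s in reversed(self.groups.values()):
            if len(s):
                return s.items[-1]
        raise RuntimeError("no growing MT to sample")


@dataclass
class Snapshot:
    time: float
    n_mt: int
    polymer: float
    mean_length: float
    free_pool: float
    Q2: float
    omega: np.ndarray
    c2: float


@dataclass
class SimulationResult:
    params: SimulationParameters
    surface: TriangulatedSurface
    snapshots: pd.DataFrame
    final_order: OrderResult | None
    final_polylines: list[np.ndarray]
    final_mt_lengths: np.ndarray
    event_log: list[tuple[float, str, int]] | None
    counters: dict[str, int]

    @property
    def final_Q2(self) -> float:
        return self.final_order.Q2 if self.final_order is not None else float("nan")

    @property
    def final_omega(self) -> np.ndarray | None:
        return self.final_order.omega if self.final_order is not None else None


# ----------------------------------------------------------------------
# The simulation
# ----------------------------------------------------------------------

class Simulation:
    """Event-driven simulation on one surface with one parameter set.

    Use :func:`run_simulation` for the standard entry point; the class is
    exposed so that unit tests can drive individual operations (nucleation,
    collision resolution, edge crossing) directly.
    """

    def __init__(self, surface: TriangulatedSurface,
                 params: SimulationParameters,
                 record_events: bool = False,
                 geometry: list[_FaceGeom] | None = None):
        params.validate()
        self.surface = surface
        self.params = params
        # the precomputed geometry tables may be shared between realizations
        # with identical surface / edge-model / face-override settings
        self.geos = (geometry if geometry is not None
                     else _build_geometry(surface, params))
        self.rng = np.random.default_rng(params.seed)
        self.record_events = record_events

        self.t = 0.0
        self.W = 0.0
        self.v_eff = params.v_plus
        self.area = surface.total_area
        self.rho_total = (params.rho_tub * self.area
                          if math.isfinite(params.rho_tub) else _INF)
        self._cum_areas = np.cumsum(surface.areas)

        # dynamic population state
        self.mts: dict[int, _MT] = {}
        self._next_id = 0
        self.n_g = 0
        self.n_s = 0
        self.SC = 0.0           # sum over alive MTs of (base + tip_off - m_off)
        self.grow_groups = _RateGroups()
        self.shrink_set = _IndexedSet()
        self.face_segs: list[_FaceRegistry] = [_FaceRegistry()
                                               for _ in range(surface.n_faces)]
        self.face_tips: list[dict] = [dict() for _ in range(surface.n_faces)]

        self._real_heap: list = []
        self._growth_heap: list = []
        self._seq = 0

        self.event_log: list[tuple[float, str, int]] | None = (
            [] if record_events else None)
        self.counters = {
            "nucleation": 0, "nucleation_blocked": 0,
            "spontaneous_catastrophe": 0, "rescue": 0,
            "zipper": 0, "crossover": 0, "induced_catastrophe": 0,
            "collision_miss": 0, "edge_crossing": 0, "edge_catastrophe": 0,
            "disappearance": 0, "vertex_clamp": 0, "events": 0,
        }

    # ------------------------------------------------------------------
    # bookkeeping primitives
    # ------------------------------------------------------------------

    def polymer(self, t: float | None = None) -> float:
        """Total polymerized MT length (um) at time t."""
        if t is None:
            t = self.t
        return (self.SC + self.n_g * self.W
                - self.n_s * self.params.v_minus * t
                - (self.n_g + self.n_s) * self.params.v_tm * t)

    def free_pool(self, t: float | None = None) -> float:
        if not math.isfinite(self.rho_total):
            return _INF
        return self.rho_total - self.polymer(t)

    def effective_growth_speed(self) -> float:
        """v_plus scaled by the free fraction of the tubulin pool."""
        if not math.isfinite(self.rho_total):
            return self.params.v_plus
        free = self.rho_total - self.polymer(self.t)
        if free < -1e-6 * max(1.0, self.rho_total):
            raise RuntimeError("tubulin pool underflow (conservation violated)")
        return self.params.v_plus * max(free, 0.0) / self.rho_total

    def _C(self, mt: _MT) -> float:
        return mt.base + mt.tip_off - mt.m_off

    def _log(self, kind: str, mt_id: int) -> None:
        if self.event_log is not None:
            self.event_log.append((self.t, kind, mt_id))

    def _S(self, mt: _MT, t: float) -> float:
        if mt.state == "g":
            return mt.tip_off + self.W
        return mt.tip_off - self.params.v_minus * t

    def _m(self, mt: _MT, t: float) -> float:
        return mt.m_off + self.params.v_tm * t

    def mt_length(self, mt: _MT, t: float | None = None) -> float:
        if t is None:
            t = self.t
        return mt.base + self._S(mt, t) - self._m(mt, t)

    # ------------------------------------------------------------------
    # event scheduling
    # ------------------------------------------------------------------

    def _push_real(self, t, kind, mt, data=None):
        self._seq += 1
        epoch = mt.epoch if mt is not None else -1
        heappush(self._real_heap, (t, self._seq, kind, mt, epoch, data))

    def _push_growth(self, Wv, kind, mt, data=None):
        self._seq += 1
        heappush(self._growth_heap, (Wv, self._seq, kind, mt, mt.epoch, data))

    def _exit_through_edge(self, mt: _MT):
        """Exit arc length, edge index and (vertex-clamped) crossing point of
        the tip ray through its triangle."""
        seg = mt.segs[-1]
        geo = self.geos[seg.face]
        px, py, ux, uy = seg.px, seg.py, seg.ux, seg.uy
        best = None
        for j in range(3):
            eg = geo.edges[j]
            ex = eg.e1x - eg.e0x
            ey = eg.e1y - eg.e0y
            det = ex * uy - ux * ey
            if det == 0.0:
                continue
            rx = eg.e0x - px
            ry = eg.e0y - py
            s = (ex * ry - rx * ey) / det
            tpar = (ux * ry - rx * uy) / det
            if s > 1e-12 and -1e-9 <= tpar <= 1.0 + 1e-9:
                if best is None or s < best[0]:
                    best = (s, tpar, j)
        if best is None:
            for j in range(3):
                eg = geo.edges[j]
                ex = eg.e1x - eg.e0x
                ey = eg.e1y - eg.e0y
                det = ex * uy - ux * ey
                if det == 0.0:
                    continue
                rx = eg.e0x - px
                ry = eg.e0y - py
                s = (ex * ry - rx * ey) / det
                tpar = (ux * ry - rx * uy) / det
                if s > -1e-9 and -1e-6 <= tpar <= 1.0 + 1e-6:
                    if best is None or s > best[0]:
                        best = (max(s, 1e-12), tpar, j)
        if best is None:
            raise RuntimeError(
                f"tip of MT {mt.id} found no exit from triangle {seg.face}")
        s, tpar, j = best
        eg = geo.edges[j]
        # deterministic vertex guard: keep the crossing point strictly inside
        # the edge by at least the geometric tolerance
        margin = GEOM_TOL / eg.elen
        tcl = min(max(tpar, margin), 1.0 - margin)
        if tcl != tpar:
            self.counters["vertex_clamp"] += 1
        cx = eg.e0x + tcl * (eg.e1x - eg.e0x)
        cy = eg.e0y + tcl * (eg.e1y - eg.e0y)
        return s, j, (cx, cy)

    def _reachable(self, oseg: _Seg, ds: float, u: float) -> bool:
        """Can the obstacle's occupied extent cover ``u`` by the time the tip
        has advanced ``ds``?  All growing tips share the same effective
        speed, so a frontier segment extends by at most ``ds`` while the tip
        covers ``ds``; candidates beyond that are unreachable and need not be
        queued.  (Occupancy is re-validated at pop time regardless.)"""
        owner = oseg.owner
        if oseg is not owner.segs[-1]:
            return True          # frozen extent already checked against LA
        if owner.state == "g":
            s_obs = owner.tip_off + self.W
        else:
            s_obs = owner.tip_off - self.params.v_minus * self.t
        return u <= s_obs + ds + _STOL

    def _predict_collisions(self, mt: _MT, s_lo: float, s_hi: float,
                            pad: float):
        """Schedule collision candidates for the tip ray in (s_lo, s_hi+pad].

        Candidates are intersections of the tip's trajectory with the
        trajectory lines of segments resident in the same triangle, pruned
        by the frozen-extent (``LA``) and reachability bounds; occupancy is
        re-validated when each candidate comes due.  Scans look ahead at
        most ``_SCAN_HORIZON`` beyond the tip; a deterministic ``scan``
        event at the window edge resumes the scan, so scheduling is only
        deferred, never altered.
        """
        seg = mt.segs[-1]
        reg = self.face_segs[seg.face]
        px, py, ux, uy = seg.px, seg.py, seg.ux, seg.uy
        tip_off = mt.tip_off
        s_hi = s_hi + pad
        n = reg.n
        if n > 8:
            EX = reg.ux[:n]
            EY = reg.uy[:n]
            det = ux * EY - uy * EX
            RX = reg.px[:n] - px
            RY = reg.py[:n] - py
            ok = np.abs(det) > 1e-12
            s = np.full(n, _INF)
            u = np.empty(n)
            np.divide(RX * EY - RY * EX, det, out=s, where=ok)
            np.divide(RX * uy - RY * ux, det, out=u, where=ok)
            mask = (ok & (s > s_lo + _STOL) & (s <= s_hi)
                    & (u > -_STOL) & (u <= reg.LA[:n] + _STOL))
            if 0 <= seg.slot < n:
                mask[seg.slot] = False
            for i in np.nonzero(mask)[0]:
                si, ui = float(s[i]), float(u[i])
                if self._reachable(reg.segs[i], si - s_lo, ui):
                    self._push_growth(si - tip_off, "coll", mt,
                                      (reg.segs[i], si, ui))
            return
        for oseg in reg.segs:
            if oseg is seg:
                continue
            ex, ey = oseg.ux, oseg.uy
            det = ux * ey - uy * ex
            if -1e-12 < det < 1e-12:
                continue   # (anti)parallel trajectories never intersect
            rx = oseg.px - px
            ry = oseg.py - py
            s = (rx * ey - ry * ex) / det
            if s <= s_lo + _STOL or s > s_hi:
                continue
            u = (rx * uy - ry * ux) / det
            if u < -_STOL:
                continue
            if u > reg.LA[oseg.slot] + _STOL:
                continue
            if self._reachable(oseg, s - s_lo, u):
                self._push_growth(s - tip_off, "coll", mt, (oseg, s, u))

    def _scan_window(self, mt: _MT, s_lo: float):
        """Scan candidates from s_lo up to the horizon; queue the next
        window-edge rescan when the exit lies beyond it."""
        if mt.s_exit - s_lo <= _SCAN_HORIZON:
            mt.horizon_s = mt.s_exit
            self._predict_collisions(mt, s_lo, mt.s_exit, _STOL)
        else:
            mt.horizon_s = s_lo + _SCAN_HORIZON
            self._predict_collisions(mt, s_lo, mt.horizon_s, 0.0)
            self._push_growth(mt.horizon_s - mt.tip_off, "scan", mt, None)

    def _notify_tips(self, newseg: _Seg):
        """New obstacle trajectory: schedule candidates for resident tips."""
        for omt in self.face_tips[newseg.face]:
            if omt is newseg.owner:
                continue
            seg = omt.segs[-1]
            ux, uy = seg.ux, seg.uy
            ex, ey = newseg.ux, newseg.uy
            det = ux * ey - uy * ex
            if -1e-12 < det < 1e-12:
                continue
            rx = newseg.px - seg.px
            ry = newseg.py - seg.py
            s = (rx * ey - ry * ex) / det
            s_now = omt.tip_off + self.W
            if s <= s_now + _STOL or s > omt.horizon_s + _STOL:
                continue   # beyond the scanned window: the rescan covers it
            u = (rx * uy - ry * ux) / det
            if u < -_STOL:
                continue
            if not self._reachable(newseg, s - s_now, u):
                continue
            self._push_growth(s - omt.tip_off, "coll", omt, (newseg, s, u))

    def _reschedule(self, mt: _MT):
        """Invalidate all pending events of this MT and schedule afresh."""
        mt.epoch += 1
        if not mt.alive:
            return
        p = self.params
        t = self.t
        if mt.state == "g":
            s_exit, j, cpt = self._exit_through_edge(mt)
            mt.s_exit = s_exit
            mt.exit_edge = j
            mt.exit_pt = cpt
            self._push_growth(s_exit - mt.tip_off, "edge", mt, None)
            self._scan_window(mt, mt.tip_off + self.W)
            if len(mt.segs) > 1:
                if p.v_tm > 0:
                    tj = (mt.segs[0].L - mt.m_off) / p.v_tm
                    self._push_real(tj, "mjunc", mt)
            else:
                # minus end can catch a (slowly) growing tip only when the
                # effective growth speed drops below the treadmilling speed;
                # the estimate is re-validated when it comes due
                if p.v_tm > 0 and self.v_eff < p.v_tm:
                    L = self.mt_length(mt, t)
                    tv = t + L / (p.v_tm - self.v_eff)
                    self._push_real(tv, "vanish", mt)
        else:
            if len(mt.segs) > 1:
                if p.v_minus > 0:
                    self._push_real(mt.tip_off / p.v_minus, "sjunc", mt)
                if p.v_tm > 0:
                    tj = (mt.segs[0].L - mt.m_off) / p.v_tm
                    self._push_real(tj, "mjunc", mt)
            else:
                denom = p.v_minus + p.v_tm
                if denom > 0:
                    tv = (mt.tip_off - mt.m_off) / denom
                    self._push_real(tv, "vanish", mt)

    # ------------------------------------------------------------------
    # state changes
    # ------------------------------------------------------------------

    def _freeze_tip(self, mt: _MT, s_now: float):
        mt.segs[-1].L = s_now

    def _to_shrinking(self, mt: _MT, kind: str):
        t = self.t
        s_now = mt.tip_off + self.W
        self._freeze_tip(mt, s_now)
        self.SC -= self._C(mt)
        mt.tip_off = s_now + self.params.v_minus * t
        mt.state = "s"
        self.SC += self._C(mt)
        self.n_g -= 1
        self.n_s += 1
        self.grow_groups.remove(mt, mt.rc)
        self.shrink_set.add(mt)
        self.face_tips[mt.segs[-1].face].pop(mt, None)
        self.counters[kind] += 1
        self._log(kind, mt.id)
        self._reschedule(mt)

    def _to_growing(self, mt: _MT):
        t = self.t
        s_now = mt.tip_off - self.params.v_minus * t
        self._freeze_tip(mt, s_now)
        self.SC -= self._C(mt)
        mt.tip_off = s_now - self.W
        mt.state = "g"
        self.SC += self._C(mt)
        self.n_g += 1
        self.n_s -= 1
        mt.rc = self.geos[mt.segs[-1].face].rc
        self.grow_groups.add(mt, mt.rc)
        self.shrink_set.remove(mt)
        self.face_tips[mt.segs[-1].face][mt] = None
        self.counters["rescue"] += 1
        self._log("rescue", mt.id)
        self._reschedule(mt)

    def _kill(self, mt: _MT):
        self.SC -= self._C(mt)
        for seg in mt.segs:
            seg.alive = False
            self.face_segs[seg.face].remove(seg)
        if mt.state == "g":
            self.n_g -= 1
            self.grow_groups.remove(mt, mt.rc)
            self.face_tips[mt.segs[-1].face].pop(mt, None)
        else:
            self.n_s -= 1
            self.shrink_set.remove(mt)
        mt.alive = False
        mt.epoch += 1
        del self.mts[mt.id]
        self.counters["disappearance"] += 1
        self._log("disappearance", mt.id)

    def _start_segment(self, mt: _MT, face: int, px: float, py: float,
                       ux: float, uy: float):
        """Freeze the current tip segment and continue in a new one."""
        s_now = mt.tip_off + self.W
        self._freeze_tip(mt, s_now)
        old_tip = mt.segs[-1]
        self.face_segs[old_tip.face].freeze(old_tip, s_now)
        mt.base += s_now
        seg = _Seg(face, px, py, ux, uy, mt)
        old_face = mt.segs[-1].face
        mt.segs.append(seg)
        mt.tip_off = -self.W          # new S starts at 0; C is unchanged
        self.face_segs[face].add(seg)
        if face != old_face:
            self.face_tips[old_face].pop(mt, None)
            self.face_tips[face][mt] = None
            new_rc = self.geos[face].rc
            if new_rc != mt.rc:
                self.grow_groups.remove(mt, mt.rc)
                mt.rc = new_rc
                self.grow_groups.add(mt, mt.rc)
        self._reschedule(mt)
        self._notify_tips(seg)

    # ------------------------------------------------------------------
    # spec-level operations
    # ------------------------------------------------------------------

    def nucleate(self) -> _MT | None:
        """Nucleate a new MT at an area-uniform random position and
        direction; a no-op when a finite tubulin pool is exhausted."""
        rng = self.rng
        if math.isfinite(self.rho_total) and self.free_pool(self.t) <= 0.0:
            self.counters["nucleation_blocked"] += 1
            self._log("nucleation_blocked", -1)
            return None
        if self.params.nucleation_weighting == "area":
            x = rng.random() * self.area
            face = int(np.searchsorted(self._cum_areas, x, side="right"))
            face = min(face, len(self.geos) - 1)
        else:
            face = int(rng.integers(len(self.geos)))
        geo = self.geos[face]
        u, v = rng.random(), rng.random()
        if u + v > 1.0:
            u, v = 1.0 - u, 1.0 - v
        (ax, ay), (bx, by), (cx, cy) = geo.verts2
        px = ax + u * (bx - ax) + v * (cx - ax)
        py = ay + u * (by - ay) + v * (cy - ay)
        ang = rng.random() * 2.0 * math.pi
        ux, uy = math.cos(ang), math.sin(ang)

        mt = _MT(self._next_id)
        self._next_id += 1
        seg = _Seg(face, px, py, ux, uy, mt)
        mt.segs.append(seg)
        mt.state = "g"
        mt.tip_off = -self.W
        mt.m_off = -self.params.v_tm * self.t
        mt.rc = geo.rc
        self.mts[mt.id] = mt
        self.SC += self._C(mt)
        self.n_g += 1
        self.grow_groups.add(mt, mt.rc)
        self.face_segs[face].add(seg)
        self.face_tips[face][mt] = None
        self.counters["nucleation"] += 1
        self._log("nucleation", mt.id)
        self._reschedule(mt)
        self._notify_tips(seg)
        return mt

    def resolve_collision(self, mt: _MT, oseg: _Seg) -> str:
        """Apply the angle-dependent collision rule; returns the outcome."""
        seg = mt.segs[-1]
        dot = seg.ux * oseg.ux + seg.uy * oseg.uy
        theta = math.acos(min(abs(dot), 1.0))
        if theta < self.params.theta_zip:
            s_now = mt.tip_off + self.W
            px = seg.px + s_now * seg.ux
            py = seg.py + s_now * seg.uy
            sign = 1.0 if dot >= 0 else -1.0
            self.counters["zipper"] += 1
            self._log("zipper", mt.id)
            self._start_segment(mt, seg.face, px, py,
                                sign * oseg.ux, sign * oseg.uy)
            return "zipper"
        if self.rng.random() < self.params.p_ic:
            self._to_shrinking(mt, "induced_catastrophe")
            return "induced_catastrophe"
        self.counters["crossover"] += 1
        self._log("crossover", mt.id)
        return "crossover"

    def edge_survival_probability(self, face: int, edge_idx: int,
                                  ux: float, uy: float) -> float:
        """Survival probability for a growing tip crossing the given edge."""
        return 1.0 - self._edge_cat_probability(face, edge_idx, ux, uy)

    def _edge_cat_probability(self, face, edge_idx, ux, uy) -> float:
        model = self.params.edge_model
        eg = self.geos[face].edges[edge_idx]
        if model.kind == "none" or not eg.tag:
            return 0.0
        if model.kind == "constant_per_class":
            return eg.p_const
        # bending-angle model: 3D angle between incoming and outgoing
        # lifted tip directions after the geodesic transition
        theta_b = self.bending_angle(face, edge_idx, ux, uy)
        return min(1.0, model.e_cat * theta_b / (math.pi / 2.0))

    def bending_angle(self, face: int, edge_idx: int,
                      ux: float, uy: float) -> float:
        """3D bending angle of a trajectory crossing the given edge."""
        geo = self.geos[face]
        eg = geo.edges[edge_idx]
        vx = eg.cos_t * ux - eg.sin_t * uy
        vy = eg.sin_t * ux + eg.cos_t * uy
        geo2 = self.geos[eg.neighbor]
        d1 = (ux * geo.ex3[0] + uy * geo.ey3[0],
              ux * geo.ex3[1] + uy * geo.ey3[1],
              ux * geo.ex3[2] + uy * geo.ey3[2])
        d2 = (vx * geo2.ex3[0] + vy * geo2.ey3[0],
              vx * geo2.ex3[1] + vy * geo2.ey3[1],
              vx * geo2.ex3[2] + vy * geo2.ey3[2])
        dot = d1[0] * d2[0] + d1[1] * d2[1] + d1[2] * d2[2]
        return math.acos(max(-1.0, min(1.0, dot)))

    def handle_edge_crossing(self, mt: _MT) -> str:
        """Growing tip reaches a triangle edge: transition or catastrophe."""
        seg = mt.segs[-1]
        eg = self.geos[seg.face].edges[mt.exit_edge]
        p_cat = self._edge_cat_probability(seg.face, mt.exit_edge,
                                           seg.ux, seg.uy)
        if p_cat > 0.0 and self.rng.random() < p_cat:
            self._to_shrinking(mt, "edge_catastrophe")
            return "edge_catastrophe"
        cx, cy = mt.exit_pt
        dx = cx - eg.ax
        dy = cy - eg.ay
        npx = eg.bx + eg.cos_t * dx - eg.sin_t * dy
        npy = eg.by + eg.sin_t * dx + eg.cos_t * dy
        vx = eg.cos_t * seg.ux - eg.sin_t * seg.uy
        vy = eg.sin_t * seg.ux + eg.cos_t * seg.uy
        norm = math.hypot(vx, vy)
        self.counters["edge_crossing"] += 1
        self._log("edge_crossing", mt.id)
        self._start_segment(mt, eg.neighbor, npx, npy, vx / norm, vy / norm)
        return "transition"

    # ------------------------------------------------------------------
    # event dispatch
    # ------------------------------------------------------------------

    def _peek_real(self):
        h = self._real_heap
        while h:
            t, _, _, mt, epoch, _ = h[0]
            if mt is None or (mt.alive and mt.epoch == epoch):
                return t
            heappop(h)
        return _INF

    def _peek_growth(self):
        h = self._growth_heap
        while h:
            Wv, _, _, mt, epoch, _ = h[0]
            if mt.alive and mt.epoch == epoch:
                if self.v_eff > 0.0:
                    return self.t + max(Wv - self.W, 0.0) / self.v_eff
                return _INF if Wv > self.W + 1e-15 else self.t
            heappop(h)
        return _INF

    def _advance(self, t_new: float):
        self.W += self.v_eff * (t_new - self.t)
        self.t = t_new

    def _total_rate(self) -> float:
        return (self.params.r_n * self.area
                + max(self.grow_groups.total, 0.0)
                + self.params.r_r * len(self.shrink_set))

    def _dispatch_stochastic(self):
        p = self.params
        rn = p.r_n * self.area
        total = self._total_rate()
        u = self.rng.random() * total
        if u < rn:
            self.nucleate()
        elif u < rn + self.grow_groups.total and self.n_g > 0:
            mt = self.grow_groups.sample(u - rn)
            self._to_shrinking(mt, "spontaneous_catastrophe")
        elif len(self.shrink_set) > 0:
            idx = int(self.rng.integers(len(self.shrink_set)))
            self._to_growing(self.shrink_set.items[idx])

    def _dispatch_real(self):
        t, _, kind, mt, epoch, data = heappop(self._real_heap)
        if mt is not None and (not mt.alive or mt.epoch != epoch):
            return False
        if kind == "meas":
            return "meas"
        if kind == "sjunc":
            seg = mt.segs.pop()
            seg.alive = False
            self.face_segs[seg.face].remove(seg)
            newtip = mt.segs[-1]
            self.face_segs[newtip.face].freeze(newtip, _INF)
            self.SC -= self._C(mt)
            mt.base -= newtip.L
            mt.tip_off = newtip.L + self.params.v_minus * self.t
            self.SC += self._C(mt)
            self._reschedule(mt)
        elif kind == "mjunc":
            seg = mt.segs.pop(0)
            seg.alive = False
            self.face_segs[seg.face].remove(seg)
            self.SC -= self._C(mt)
            mt.base -= seg.L
            mt.m_off = -self.params.v_tm * self.t
            self.SC += self._C(mt)
            self._reschedule(mt)
        elif kind == "vanish":
            if self.mt_length(mt, self.t) <= _LTOL:
                self._kill(mt)
            else:
                self._reschedule(mt)
        return True

    def _dispatch_growth(self):
        Wv, _, kind, mt, epoch, data = heappop(self._growth_heap)
        if not mt.alive or mt.epoch != epoch:
            return
        if kind == "edge":
            self.handle_edge_crossing(mt)
        elif kind == "scan":
            self._scan_window(mt, mt.horizon_s)
        else:  # collision candidate
            oseg, s, u = data
            outcome = "miss"
            if oseg.alive:
                owner = oseg.owner
                hi = (self._S(owner, self.t) if oseg is owner.segs[-1]
                      else oseg.L)
                lo = self._m(owner, self.t) if oseg is owner.segs[0] else 0.0
                if lo - _STOL <= u <= hi + _STOL:
                    outcome = self.resolve_collision(mt, oseg)
            if outcome == "miss":
                self.counters["collision_miss"] += 1
                self._log("collision_miss", mt.id)

    # ------------------------------------------------------------------
    # main loop
    # ------------------------------------------------------------------

    def add_initial_mt(self, face: int, point, direction, length: float = 0.0,
                       state: str = "g") -> _MT:
        """Place an MT explicitly (for tests and micro-scenarios).

        ``point`` is the minus-end position in the chart of ``face``;
        the plus end lies ``length`` um along ``direction``.
        """
        if self.t != 0.0:
            raise RuntimeError("initial MTs must be added before running")
        ux, uy = direction
        norm = math.hypot(ux, uy)
        mt = _MT(self._next_id)
        self._next_id += 1
        seg = _Seg(face, float(point[0]), float(point[1]),
                   ux / norm, uy / norm, mt)
        seg.L = length
        mt.segs.append(seg)
        mt.state = state[0]
        if mt.state == "g":
            mt.tip_off = length - self.W
        else:
            mt.tip_off = length
        mt.m_off = 0.0
        mt.rc = self.geos[face].rc
        self.mts[mt.id] = mt
        self.SC += self._C(mt)
        if mt.state == "g":
            self.n_g += 1
            self.grow_groups.add(mt, mt.rc)
            self.face_tips[face][mt] = None
        else:
            self.n_s += 1
            self.shrink_set.add(mt)
        self.face_segs[face].add(seg)
        self._reschedule(mt)
        self._notify_tips(seg)
        return mt

    def run(self, store_snapshots: bool = True,
            final_polylines: bool = True) -> SimulationResult:
        p = self.params
        duration = p.duration
        times = list(np.arange(p.measure_interval, duration,
                               p.measure_interval))
        times.append(duration)
        for tm in times:
            self._push_real(float(tm), "meas", None)

        snapshots: list[Snapshot] = []
        rng = self.rng
        while True:
            self.v_eff = self.effective_growth_speed()
            R = self._total_rate()
            t_st = self.t + rng.exponential() / R if R > 0 else _INF
            t_re = self._peek_real()
            t_gr = self._peek_growth()
            if t_re <= t_gr and t_re <= t_st:
                self._advance(t_re)
                out = self._dispatch_real()
                if out == "meas":
                    if store_snapshots or self.t >= duration:
                        snapshots.append(self._snapshot())
                    if self.t >= duration:
                        break
                if out:
                    self.counters["events"] += 1
            elif t_gr <= t_st:
                self._advance(t_gr)
                self._dispatch_growth()
                self.counters["events"] += 1
            else:
                if t_st > duration:
                    # no stochastic event before the horizon; deterministic
                    # queue will carry us to the final measurement
                    continue
                self._advance(t_st)
                self._dispatch_stochastic()
                self.counters["events"] += 1

        return self._result(snapshots, final_polylines)

    # ------------------------------------------------------------------
    # measurement
    # ------------------------------------------------------------------

    def _segment_extents(self, mt: _MT):
        t = self.t
        S = max(self._S(mt, t), 0.0)
        m = max(self._m(mt, t), 0.0)
        out = []
        n = len(mt.segs)
        for i, seg in enumerate(mt.segs):
            hi = S if i == n - 1 else seg.L
            lo = m if i == 0 else 0.0
            if hi - lo > 1e-12:
                out.append((seg, lo, hi))
        return out

    def _snapshot(self) -> Snapshot:
        dirs = []
        lens = []
        lengths_per_mt = []
        for mt in self.mts.values():
            total = 0.0
            for seg, lo, hi in self._segment_extents(mt):
                geo = self.geos[seg.face]
                dirs.append((seg.ux * geo.ex3[0] + seg.uy * geo.ey3[0],
                             seg.ux * geo.ex3[1] + seg.uy * geo.ey3[1],
                             seg.ux * geo.ex3[2] + seg.uy * geo.ey3[2]))
                lens.append(hi - lo)
                total += hi - lo
            if total > 0:
                lengths_per_mt.append(total)
        polymer = self.polymer()
        free = self.free_pool()
        if lens:
            res = order_tensor(np.array(dirs), np.array(lens))
            q2, omega = res.Q2, res.omega
            c2 = float(omega[2] ** 2 - 0.5 * (omega[0] ** 2 + omega[1] ** 2))
        else:
            q2, omega, c2 = float("nan"), np.full(3, np.nan), float("nan")
        mean_len = (float(np.mean(lengths_per_mt))
                    if lengths_per_mt else float("nan"))
        return Snapshot(time=self.t, n_mt=len(lengths_per_mt),
                        polymer=polymer, mean_length=mean_len,
                        free_pool=free, Q2=q2, omega=omega, c2=c2)

    def mt_polylines(self) -> tuple[list[np.ndarray], np.ndarray]:
        """Current MT shapes lifted to 3D; returns (polylines, lengths)."""
        polylines = []
        lengths = []
        for mt in self.mts.values():
            pts = []
            total = 0.0
            for seg, lo, hi in self._segment_extents(mt):
                geo = self.geos[seg.face]
                for s, first in ((lo, True), (hi, False)):
                    x = seg.px + s * seg.ux
                    y = seg.py + s * seg.uy
                    p3 = (x * geo.ex3[0] + y * geo.ey3[0] + geo.z0 * geo.ez3[0],
                          x * geo.ex3[1] + y * geo.ey3[1] + geo.z0 * geo.ez3[1],
                          x * geo.ex3[2] + y * geo.ey3[2] + geo.z0 * geo.ez3[2])
                    if first and pts:
                        continue   # junction point already present
                    pts.append(p3)
                total += hi - lo
            if total > 0:
                polylines.append(np.asarray(pts))
                lengths.append(total)
        return polylines, np.asarray(lengths)

    def _result(self, snapshots: list[Snapshot],
                final_polylines: bool) -> SimulationResult:
        rows = [{
            "time": s.time, "n_mt": s.n_mt, "polymer": s.polymer,
            "mean_length": s.mean_length, "free_pool": s.free_pool,
            "Q2": s.Q2, "omega_x": s.omega[0], "omega_y": s.omega[1],
            "omega_z": s.omega[2], "C2": s.c2,
        } for s in snapshots]
        df = pd.DataFrame(rows)
        polylines, lengths = self.mt_polylines() if final_polylines else ([], np.array([]))
        final_order = None
        if len(lengths):
            dirs, lens = [], []
            for pts in polylines:
                segd = np.diff(pts, axis=0)
                dirs.append(segd)
                lens.append(np.linalg.norm(segd, axis=1))
            final_order = order_tensor(np.vstack(dirs), np.concatenate(lens))
        return SimulationResult(
            params=self.params, surface=self.surface, snapshots=df,
            final_order=final_order, final_polylines=polylines,
            final_mt_lengths=lengths, event_log=self.event_log,
            counters=dict(self.counters))


def run_simulation(surface: TriangulatedSurface, params: SimulationParameters,
                   initial_mts=None, record_events: bool = False,
                   store_snapshots: bool = True,
                   geometry=None) -> SimulationResult:
    """Run one realization of the MT dynamics on the given surface.

    Identical (surface, params, seed) inputs reproduce the identical event
    sequence.  ``initial_mts`` is an optional list of
    ``(face, point2d, direction2d, length, state)`` tuples placed before the
    clock starts (used by micro-scenario tests).
    """
    sim = Simulation(surface, params, record_events=record_events,
                     geometry=geometry)
    if initial_mts:
        for spec in initial_mts:
            sim.add_initial_mt(*spec)
    return sim.run(store_snapshots=store_snapshots)
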