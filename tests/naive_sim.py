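"""Independent fixed-timestep reference simulator for micro-scenarios.

Brute-force time stepper for a handful of MTs confined to a single planar
region: every step, tips advance by v*dt and collisions are detected by
explicit segment-segment intersection against the other MTs' current
polylines.  No event queues, no trajectory bookkeeping — this is the slow,
obvious implementation used as an oracle for the event-driven engine.

Stochastic rates are zero by construction; collision outcomes are made
deterministic by using p_ic in {0, 1}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass
class NaiveMT:
    points: list          # polyline vertices, minus end first (list of [x, y])
    direction: tuple      # current tip direction (unit)
    state: str = "g"      # "g" growing / "s" shrinking
    alive: bool = True
    crossed: set = field(default_factory=set)   # obstacle ids passed over


def _seg_intersect(p, q, a, b):
    """Intersection of segment p->q with segment a->b.

    Returns (s, u) with s, u in [0, 1] parametrising p->q and a->b, or None.
    """
    dx, dy = q[0] - p[0], q[1] - p[1]
    ex, ey = b[0] - a[0], b[1] - a[1]
    det = dx * ey - dy * ex
    if abs(det) < 1e-14:
        return None
    rx, ry = a[0] - p[0], a[1] - p[1]
    s = (rx * ey - ry * ex) / det
    u = (rx * dy - ry * dx) / det
    if -1e-12 <= s <= 1 + 1e-12 and -1e-12 <= u <= 1 + 1e-12:
        return s, u
    return None


def _length(points):
    return sum(math.hypot(points[i + 1][0] - points[i][0],
                          points[i + 1][1] - points[i][1])
               for i in range(len(points) - 1))


class NaiveSimulator:
    def __init__(self, mts, v_plus=0.08, v_minus=0.16, v_tm=0.01,
                 theta_zip=math.radians(40.0), p_ic=1.0, dt=1e-4):
        """``mts``: list of (minus_point, direction, length, state)."""
        self.mts = []
        for point, direction, length, state in mts:
            norm = math.hypot(*direction)
            d = (direction[0] / norm, direction[1] / norm)
            tip = [point[0] + length * d[0], point[1] + length * d[1]]
            self.mts.append(NaiveMT(points=[list(point), tip], direction=d,
                                    state=state[0]))
        self.v_plus = v_plus
        self.v_minus = v_minus
        self.v_tm = v_tm
        self.theta_zip = theta_zip
        self.p_ic = p_ic
        self.dt = dt
        self.t = 0.0
        self.events = []   # (time, kind, mt_index)

    # ------------------------------------------------------------------
    def _advance_tip(self, i, mt):
        d = mt.direction
        step = self.v_plus * self.dt
        old = mt.points[-1]
        new = [old[0] + step * d[0], old[1] + step * d[1]]
        # earliest collision with any other MT's polyline (and own older
        # segments, excluding the two most recent own segments)
        best = None
        for j, other in enumerate(self.mts):
            if not other.alive:
                continue
            pts = other.points
            n_seg = len(pts) - 1
            for k in range(n_seg):
                if j == i and k >= n_seg - 2:
                    continue   # own current/adjacent segment
                hit = _seg_intersect(old, new, pts[k], pts[k + 1])
                if hit is None:
                    continue
                s, u = hit
                if s < 1e-9:
                    continue
                key = (j, round(pts[k][0] + u * (pts[k + 1][0] - pts[k][0]), 6),
                       round(pts[k][1] + u * (pts[k + 1][1] - pts[k][1]), 6))
                if key in mt.crossed:
                    continue
                if best is None or s < best[0]:
                    ex, ey = pts[k + 1][0] - pts[k][0], pts[k + 1][1] - pts[k][1]
                    best = (s, key, (ex, ey))
        if best is None:
            mt.points[-1] = new
            return
        s, key, (ex, ey) = best
        cx = old[0] + s * step * d[0]
        cy = old[1] + s * step * d[1]
        en = math.hypot(ex, ey)
        e = (ex / en, ey / en)
        dot = d[0] * e[0] + d[1] * e[1]
        theta = math.acos(min(abs(dot), 1.0))
        if theta < self.theta_zip:
            sign = 1.0 if dot >= 0 else -1.0
            mt.points[-1] = [cx, cy]
            mt.points.append([cx, cy])
            mt.direction = (sign * e[0], sign * e[1])
            self.events.append((self.t, "zipper", i))
        elif self.p_ic >= 0.5:
            mt.points[-1] = [cx, cy]
            mt.state = "s"
            self.events.append((self.t, "induced_catastrophe", i))
        else:
            mt.crossed.add(key)
            mt.points[-1] = new
            self.events.append((self.t, "crossover", i))

    def _retreat_tip(self, mt):
        left = self.v_minus * self.dt
        pts = mt.points
        while left > 0 and len(pts) > 1:
            seg = math.hypot(pts[-1][0] - pts[-2][0], pts[-1][1] - pts[-2][1])
            if seg > left:
                f = (seg - left) / seg
                pts[-1] = [pts[-2][0] + f * (pts[-1][0] - pts[-2][0]),
                           pts[-2][1] + f * (pts[-1][1] - pts[-2][1])]
                if len(pts) > 2:
                    dx = pts[-1][0] - pts[-2][0]
                    dy = pts[-1][1] - pts[-2][1]
                    n = math.hypot(dx, dy)
                    if n > 1e-12:
                        mt.direction = (dx / n, dy / n)
                return
            left -= seg
            pts.pop()
            if len(pts) > 1:
                dx = pts[-1][0] - pts[-2][0]
                dy = pts[-1][1] - pts[-2][1]
                n = math.hypot(dx, dy)
                if n > 1e-12:
                    mt.direction = (dx / n, dy / n)

    def _treadmill(self, mt):
        left = self.v_tm * self.dt
        pts = mt.points
        while left > 0 and len(pts) > 1:
            seg = math.hypot(pts[1][0] - pts[0][0], pts[1][1] - pts[0][1])
            if seg > left:
                f = left / seg
                pts[0] = [pts[0][0] + f * (pts[1][0] - pts[0][0]),
                          pts[0][1] + f * (pts[1][1] - pts[0][1])]
                return
            left -= seg
            pts.pop(0)

    def run(self, duration):
        n_steps = int(round(duration / self.dt))
        for _ in range(n_steps):
            self.t += self.dt
            for i, mt in enumerate(self.mts):
                if not mt.alive:
                    continue
                if mt.state == "g":
                    self._advance_tip(i, mt)
                else:
                    self._retreat_tip(mt)
                self._treadmill(mt)
                if _length(mt.points) < max(
                        1e-9, (self.v_minus + self.v_tm) * self.dt * 1.5):
                    if mt.state == "s" or self.v_tm > self.v_plus:
                        mt.alive = False
                        self.events.append((self.t, "disappearance", i))
        return self.events

    def lengths(self):
        return [_length(mt.points) if mt.alive else 0.0 for mt in self.mts]

    def tips(self):
        return [tuple(mt.points[-1]) if mt.alive else None for mt in self.mts]
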