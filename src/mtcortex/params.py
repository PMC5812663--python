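"""Simulation parameters for cortical microtubule dynamics.

Default single-MT dynamics values follow the established event-driven
cortical-array modelling framework: growth speed v+ = 0.08 um/s, shrinkage
speed v- = 0.16 um/s, treadmilling speed v_tm = 0.01 um/s, rescue rate
r_r = 0.007 /s, nucleation rate r_n = 0.01 /(s um^2).  The spontaneous
catastrophe rate defaults to the working-point value that yields an
interaction-free mean length l_avg = 417.5 um (bounded-growth regime,
G ~ -0.005).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace


def rc_for_mean_length(l_avg: float, v_plus: float = 0.08, v_minus: float = 0.16,
                       v_tm: float = 0.01, r_r: float = 0.007) -> float:
    """Spontaneous catastrophe rate giving interaction-free mean length l_avg.

    Inverts 1/l_avg = r_c/(v+ - v_tm) - r_r/(v- + v_tm).
    """
    return (v_plus - v_tm) * (1.0 / l_avg + r_r / (v_minus + v_tm))


@dataclass
class EdgeModel:
    """Edge-catastrophe rule applied when a growing tip crosses a cell edge.

    kind:
      * ``"none"`` — tips always survive edge crossings.
      * ``"constant_per_class"`` — catastrophe with a fixed probability per
        edge class (e.g. P_transverse / P_longitudinal on the cube),
        given in ``class_probabilities``.
      * ``"bending_angle"`` — catastrophe probability
        min(1, E_cat * theta_b / (pi/2)), where theta_b is the 3D bending
        angle between the incoming and outgoing lifted tip directions at the
        crossing.  Only edges tagged as cell edges are eligible.
    """

    kind: str = "none"
    class_probabilities: dict[str, float] = field(default_factory=dict)
    e_cat: float = 0.5

    def validate(self) -> None:
        if self.kind not in ("none", "constant_per_class", "bending_angle"):
            raise ValueError(f"unknown edge model kind {self.kind!r}")
        for cls, p in self.class_probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"edge probability for {cls!r} outside [0, 1]")
        if self.e_cat < 0:
            raise ValueError("e_cat must be non-negative")


@dataclass
class SimulationParameters:
    """All rates, speeds, interaction thresholds and run controls.

    Speeds are in um/s, rates in 1/s (nucleation in 1/(s um^2)), angles in
    radians, durations in seconds of biological time.  ``rho_tub`` is the
    tubulin pool density in um of polymer per um^2 of surface;
    ``math.inf`` disables the finite-pool (homeostatic growth speed) effect.
    """

    v_plus: float = 0.08
    v_minus: float = 0.16
    v_tm: float = 0.01
    r_c: float = rc_for_mean_length(417.5)
    r_r: float = 0.007
    r_n: float = 0.01
    theta_zip: float = math.radians(40.0)
    p_ic: float = 0.5
    edge_model: EdgeModel = field(default_factory=EdgeModel)
    rc_face_overrides: dict[int, float] = field(default_factory=dict)
    rho_tub: float = math.inf
    duration: float = 36000.0
    measure_interval: float = 300.0
    seed: int = 0
    nucleation_weighting: str = "area"   # "area" (spatially uniform) or "triangle"

    def validate(self) -> None:
        if min(self.v_plus, self.v_minus, self.v_tm) < 0:
            raise ValueError("speeds must be non-negative")
        if self.v_plus <= self.v_tm:
            raise ValueError("v_plus must exceed v_tm (no net growth otherwise)")
        if min(self.r_c, self.r_r, self.r_n) < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.p_ic <= 1.0:
            raise ValueError("p_ic must lie in [0, 1]")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.rho_tub <= 0:
            raise ValueError("rho_tub must be positive (use math.inf for none)")
        if self.nucleation_weighting not in ("area", "triangle"):
            raise ValueError("nucleation_weighting must be 'area' or 'triangle'")
        self.edge_model.validate()
        for tag, rc in self.rc_face_overrides.items():
            if rc < 0:
                raise ValueError(f"negative r_c override for face tag {tag}")

    def with_overrides(self, **kwargs) -> "SimulationParameters":
        return replace(self, **kwargs)


def set_face_overrides(params: SimulationParameters,
                       overrides: dict[int, float]) -> SimulationParameters:
    """Return parameters with per-face-tag spontaneous catastrophe rates.

    A growing tip uses the r_c of the face tag of its current triangle; the
    override takes effect as soon as the tip crosses into a triangle of a
    different face.
    """
    new = dict(params.rc_face_overrides)
    new.update({int(k): float(v) for k, v in overrides.items()})
    p = params.with_overrides(rc_face_overrides=new)
    p.validate()
    return p
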