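"""Preset study conditions for the validation geometries.

Each preset returns a (surface, parameters) pair reproducing one of the
standard numerical experiments:

* sphere at the working point (ordered array, G ~ -0.005, finite pool),
* cube with constant per-class edge-catastrophe probabilities,
* rounded cuboid probing the interplay of shape, edge-catastrophe and
  face-specific MT stability.

The single-MT dynamics parameters are shared: v+ = 0.08, v- = 0.16,
v_tm = 0.01 um/s, r_r = 0.007 /s, r_n = 0.01 /(s um^2); the spontaneous
catastrophe rate is set through the interaction-free mean length l_avg.
Durations are the package's standard problem sizes; pass ``duration``
explicitly for longer or shorter runs.
"""

from __future__ import annotations

import math

from .generators import make_cube, make_rounded_cuboid, make_sphere
from .params import EdgeModel, SimulationParameters, rc_for_mean_length
from .surface import TriangulatedSurface

#: working-point interaction-free mean length (um); G ~ -0.005
WORKING_LAVG = 417.5

#: tubulin pool density (um of polymer per um^2 of surface) used with the
#: homeostatic growth-speed control
WORKING_RHO_TUB = 10.0


def working_point_params(l_avg: float = WORKING_LAVG,
                         rho_tub: float = WORKING_RHO_TUB,
                         duration: float = 10800.0,
                         measure_interval: float = 300.0,
                         seed: int = 0) -> SimulationParameters:
    """Parameters at the ordering working point (bounded growth, G < 0)."""
    return SimulationParameters(
        r_c=rc_for_mean_length(l_avg),
        rho_tub=rho_tub,
        duration=duration,
        measure_interval=measure_interval,
        seed=seed,
    )


def sphere_working_point(radius: float = 6.0, n_triangles: int = 1280,
                         method: str = "icosphere", **kwargs
                         ) -> tuple[TriangulatedSurface, SimulationParameters]:
    """Sphere of radius ~6 um (embryonic-cell scale) at the working point."""
    surface = make_sphere(radius, n_triangles, method=method)
    return surface, working_point_params(**kwargs)


def cube_scenario(P_perp: float = 0.26, P_par: float = 0.26,
                  side: float = 15.0, l_avg: float = WORKING_LAVG,
                  duration: float = 10800.0, seed: int = 0
                  ) -> tuple[TriangulatedSurface, SimulationParameters]:
    """Cube with constant edge-catastrophe probabilities per edge class.

    ``P_perp`` applies to the 8 transverse cube edges (bordering top and
    bottom), ``P_par`` to the 4 longitudinal side edges.  The tubulin pool is
    infinite for this scenario.
    """
    surface = make_cube(side)
    params = SimulationParameters(
        r_c=rc_for_mean_length(l_avg),
        edge_model=EdgeModel(kind="constant_per_class",
                             class_probabilities={"transverse": P_perp,
                                                  "longitudinal": P_par}),
        rho_tub=math.inf,
        duration=duration,
        measure_interval=300.0,
        seed=seed,
    )
    return surface, params


# rounded-cuboid face tags produced by make_rounded_cuboid: flat faces are
# numbered by (axis, sign): 1,2 = b x c faces (normal +-x), 3,4 = a x c faces
# (normal +-y), 5,6 = a x b faces (normal +-z); 0 = rounded strips.
CUBOID_AC_FACE_TAGS = (3, 4)


def cuboid_surface(a: float = 13.0, b: float = 7.5, c: float = 5.0,
                   rounding: float = 1.0, n_triangles: int = 1280
                   ) -> TriangulatedSurface:
    return make_rounded_cuboid(a, b, c, rounding=rounding,
                               n_triangles=n_triangles)


def cuboid_default(l_avg: float = WORKING_LAVG,
                   rho_tub: float = WORKING_RHO_TUB,
                   duration: float = 10800.0, seed: int = 0,
                   n_triangles: int = 1280
                   ) -> tuple[TriangulatedSurface, SimulationParameters]:
    """Rounded cuboid 13 x 7.5 x 5 um, default dynamics (no edge or face
    effects); the steady-state simulated mean length is ~4.5 um."""
    surface = cuboid_surface(n_triangles=n_triangles)
    params = SimulationParameters(
        r_c=rc_for_mean_length(l_avg),
        rho_tub=rho_tub,
        duration=duration,
        measure_interval=300.0,
        seed=seed,
    )
    return surface, params


def cuboid_edge_catastrophe(e_cat: float = 0.5, **kwargs
                            ) -> tuple[TriangulatedSurface, SimulationParameters]:
    """Rounded cuboid with the bending-angle edge-catastrophe model applied
    to the rounded strips (multiplier E_cat)."""
    surface, params = cuboid_default(**kwargs)
    params = params.with_overrides(
        edge_model=EdgeModel(kind="bending_angle", e_cat=e_cat))
    return surface, params


def cuboid_protected_faces(protected_l_avg: float = WORKING_LAVG,
                           other_l_avg: float = 40.0, **kwargs
                           ) -> tuple[TriangulatedSurface, SimulationParameters]:
    """Rounded cuboid with enhanced MT stability on the two a x c faces.

    The spontaneous catastrophe rate is raised everywhere except on the
    protected a x c faces, lowering the simulated mean MT length there
    (~3.5 um vs ~4.5 um on the protected faces).  ``other_l_avg`` sets the
    interaction-free mean length implied by the raised rate.
    """
    surface, params = cuboid_default(**kwargs)
    rc_protected = rc_for_mean_length(protected_l_avg)
    rc_other = rc_for_mean_length(other_l_avg)
    overrides = {tag: rc_other for tag in range(0, 7)
                 if tag not in CUBOID_AC_FACE_TAGS}
    params = params.with_overrides(r_c=rc_protected,
                                   rc_face_overrides=overrides)
    return surface, params
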