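"""Nematic order metrics for microtubule configurations.

The global degree of order is measured by the tensor

    Q = 3 <u u^T>_L - I,

where <.>_L is the length-weighted average over the 3D unit direction
vectors of all MT segments (directions are nematic: u and -u are
equivalent, and u u^T makes this automatic).  Q is symmetric and traceless.
The scalar order parameter Q2 is the absolute value of the smallest
eigenvalue and the array orientation Omega is the corresponding unit
eigenvector:

* isotropic 3D directions     -> Q2 ~ 0,
* any perfectly planar array  -> Q2 = 1 with Omega normal to the array plane.

For the cubic geometry the orientation is summarised by
C2 = Omega_z^2 - (Omega_x^2 + Omega_y^2)/2 = (3 Omega_z^2 - 1)/2, which is 1
for a transverse array (wrapping the top-bottom axis) and -1/2 for a
longitudinal one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class OrderResult:
    """Order tensor with its smallest eigenpair.

    ``omega`` is sign-ambiguous (nematic); it is canonicalized so its first
    nonzero component is positive.  ``total_weight`` is the total MT length
    (um) that entered the average.
    """

    tensor: np.ndarray        # symmetric traceless 3x3
    Q2: float                 # |smallest eigenvalue|
    omega: np.ndarray         # unit eigenvector of the smallest eigenvalue
    total_weight: float


def _canonicalize(v: np.ndarray) -> np.ndarray:
    for x in v:
        if abs(x) > 1e-12:
            return v if x > 0 else -v
    return v


def order_tensor(directions: np.ndarray, lengths: np.ndarray) -> OrderResult:
    """Compute the order tensor from 3D segment directions and lengths.

    Parameters
    ----------
    directions : (N, 3) array
        Segment direction vectors (need not be normalized; zero rows with
        zero length are allowed and ignored).
    lengths : (N,) array
        Segment lengths (um), used as weights.
    """
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    lengths = np.asarray(lengths, dtype=float).ravel()
    total = float(lengths.sum())
    if total <= 0:
        raise ValueError("zero total MT length: order tensor undefined")
    norms = np.linalg.norm(directions, axis=1)
    keep = norms > 0
    u = directions[keep] / norms[keep, None]
    w = lengths[keep] / total
    second_moment = (w[:, None, None] * u[:, :, None] * u[:, None, :]).sum(axis=0)
    tensor = 3.0 * second_moment - np.eye(3)
    evals, evecs = np.linalg.eigh(tensor)
    # eigh returns ascending eigenvalues; the smallest is the first
    q2 = float(abs(evals[0]))
    omega = _canonicalize(evecs[:, 0].copy())
    return OrderResult(tensor=tensor, Q2=q2, omega=omega, total_weight=total)


def order_from_polylines(polylines) -> OrderResult:
    """Order tensor from a list of (N, 3) MT polylines."""
    dirs, lens = [], []
    for pts in polylines:
        pts = np.asarray(pts, dtype=float)
        seg = np.diff(pts, axis=0)
        dirs.append(seg)
        lens.append(np.linalg.norm(seg, axis=1))
    if not dirs:
        raise ValueError("no polylines given")
    return order_tensor(np.vstack(dirs), np.concatenate(lens))


def c2_from_omega(omega: np.ndarray) -> float:
    """Cube orientation score C2 = (3 Omega_z^2 - 1)/2 for a unit vector.

    1 for a transverse array (omega along z), -1/2 for a longitudinal one
    (omega in the x-y plane); sign-invariant under omega -> -omega.
    """
    omega = np.asarray(omega, dtype=float).ravel()
    if abs(np.linalg.norm(omega) - 1.0) > 1e-6:
        raise ValueError("omega must be a unit vector")
    return float(omega[2] ** 2 - 0.5 * (omega[0] ** 2 + omega[1] ** 2))


def control_G(v_plus: float = 0.08, v_minus: float = 0.16, v_tm: float = 0.01,
              r_c: float = 0.00305, r_r: float = 0.007, r_n: float = 0.01,
              l_0: float | None = None, l_avg: float | None = None,
              ) -> tuple[float, float, float]:
    """Control parameter G = -l_0 / l_avg of interaction-driven ordering.

    l_0 = (2 (v+ - v_tm)(v- + v_tm) / (r_n (v+ + v-)))^(1/3) is the MT-MT
    interaction length; 1/l_avg = r_c/(v+ - v_tm) - r_r/(v- + v_tm) is the
    inverse interaction-free mean MT length.  G < 0 is the bounded-growth
    regime; for l_avg <= 0 (unbounded growth) G >= 0 is returned with a
    warning.

    Either length may be supplied directly via ``l_0`` / ``l_avg``, bypassing
    the rate-based formulas.

    Returns
    -------
    (l_0, l_avg, G)
    """
    if l_0 is None:
        if v_plus <= v_tm:
            raise ValueError("v_plus must exceed v_tm")
        l_0 = (2.0 * (v_plus - v_tm) * (v_minus + v_tm)
               / (r_n * (v_plus + v_minus))) ** (1.0 / 3.0)
    if l_avg is None:
        inv = r_c / (v_plus - v_tm) - r_r / (v_minus + v_tm)
        if inv == 0:
            raise ValueError("l_avg diverges: r_c/(v+-v_tm) == r_r/(v-+v_tm)")
        l_avg = 1.0 / inv
    G = -l_0 / l_avg
    if G >= 0:
        warnings.warn("unbounded-growth inputs: l_avg <= 0 gives G >= 0")
    return float(l_0), float(l_avg), float(G)


def mean_mt_length(lengths) -> float:
    """Arithmetic mean of per-MT total lengths (um)."""
    lengths = np.asarray(list(lengths), dtype=float)
    if lengths.size == 0:
        raise ValueError("no microtubules: mean length undefined")
    return float(lengths.mean())
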