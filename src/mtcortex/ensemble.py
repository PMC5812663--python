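"""Seeded ensembles of realizations and directional statistics of the
resulting array orientations.

Array orientations are nematic directors (Omega and -Omega are the same
physical orientation), so before any statistics they are folded antipodally.
Clustering uses agglomerative (average-linkage) hierarchical clustering with
the angular distance d(u, v) = arccos|u . v|, following the standard
``scipy.cluster.hierarchy.fcluster`` workflow; isotropy on the sphere is
assessed by a chi-squared test on an equal-area (Lambert azimuthal)
projection of the folded director tips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import chisquare

from .engine import _build_geometry, run_simulation
from .order import c2_from_omega
from .params import SimulationParameters
from .surface import TriangulatedSurface

#: realizations whose director is further than this (radians) from every
#: cluster mean are reported as unclustered outliers
OUTLIER_ANGLE = math.radians(30.0)

#: cube-outcome thresholds: midpoints between the anchor values
#: C2 = 1 (transverse), 0 (mixed) and -1/2 (longitudinal)
C2_TRANSVERSE_THRESHOLD = 0.5
C2_LONGITUDINAL_THRESHOLD = -0.25


@dataclass
class EnsembleResult:
    """Per-realization final summaries of a seeded ensemble."""

    table: pd.DataFrame            # seed, Q2, omega_*, C2, mean_length, n_mt
    params: SimulationParameters
    n_realizations: int
    failures: list[tuple[int, str]] = field(default_factory=list)

    @property
    def omegas(self) -> np.ndarray:
        return self.table[["omega_x", "omega_y", "omega_z"]].to_numpy()

    @property
    def Q2(self) -> np.ndarray:
        return self.table["Q2"].to_numpy()


def run_ensemble(surface: TriangulatedSurface, params: SimulationParameters,
                 n: int, base_seed: int = 0,
                 keep_results: bool = False) -> EnsembleResult:
    """Run ``n`` independent realizations with seeds base_seed .. base_seed+n-1.

    Realizations are mutually independent (order-independent, parallelizable);
    a failed realization is recorded in ``failures`` rather than silently
    dropped.
    """
    if n < 1:
        raise ValueError("ensemble size must be at least 1")
    geometry = _build_geometry(surface, params)
    rows = []
    failures = []
    results = []
    for i in range(n):
        seed = base_seed + i
        p = params.with_overrides(seed=seed)
        try:
            res = run_simulation(surface, p, store_snapshots=False,
                                 geometry=geometry)
        except Exception as exc:   # noqa: BLE001 - recorded, not dropped
            failures.append((seed, repr(exc)))
            continue
        omega = res.final_omega
        row = {"seed": seed, "Q2": res.final_Q2,
               "n_mt": len(res.final_mt_lengths),
               "mean_length": (float(res.final_mt_lengths.mean())
                               if len(res.final_mt_lengths) else float("nan"))}
        if omega is not None:
            row.update(omega_x=omega[0], omega_y=omega[1], omega_z=omega[2],
                       C2=c2_from_omega(omega))
        else:
            row.update(omega_x=np.nan, omega_y=np.nan, omega_z=np.nan,
                       C2=np.nan)
        rows.append(row)
        if keep_results:
            results.append(res)
    ens = EnsembleResult(table=pd.DataFrame(rows), params=params,
                         n_realizations=n, failures=failures)
    if keep_results:
        ens.results = results
    return ens


# ----------------------------------------------------------------------
# Directional statistics
# ----------------------------------------------------------------------

def fold_directors(omegas: np.ndarray) -> np.ndarray:
    """Fold nematic directors to the z >= 0 hemisphere (antipodal symmetry)."""
    omegas = np.atleast_2d(np.asarray(omegas, dtype=float))
    omegas = omegas / np.linalg.norm(omegas, axis=1, keepdims=True)
    flip = omegas[:, 2] < 0
    out = omegas.copy()
    out[flip] *= -1.0
    return out


@dataclass
class OrientationClustering:
    folded: np.ndarray             # (n, 3) folded unit directors
    labels: np.ndarray             # cluster label per realization; 0 = outlier
    means: np.ndarray              # (k, 3) unit mean orientation per cluster
    counts: np.ndarray             # member count per cluster
    fractions: np.ndarray          # counts / n (outliers excluded)
    n: int


def cluster_orientations(omegas: np.ndarray, k: int,
                         outlier_angle: float = OUTLIER_ANGLE
                         ) -> OrientationClustering:
    """Agglomerative clustering of array orientations into ``k`` clusters.

    Directors are folded by nematic symmetry first; the pairwise distance is
    the angle arccos|u . v|.  Cluster means are the dominant eigenvector of
    the members' orientation second-moment matrix.  Members further than
    ``outlier_angle`` from their cluster mean are moved to an outlier bucket
    (label 0), so fractions sum to <= 1.
    """
    folded = fold_directors(omegas)
    n = len(folded)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"cannot form {k} clusters from {n} orientations")
    if k == 1 or n == 1:
        raw = np.ones(n, dtype=int)
    else:
        d = pdist(folded, metric=lambda u, v: math.acos(
            min(abs(float(np.dot(u, v))), 1.0)))
        raw = fcluster(linkage(d, method="average"), t=k, criterion="maxclust")

    means = []
    labels = np.zeros(n, dtype=int)
    for c in range(1, int(raw.max()) + 1):
        members = folded[raw == c]
        if len(members) == 0:
            continue
        m2 = members.T @ members
        _, vecs = np.linalg.eigh(m2)
        mean = vecs[:, -1]
        if mean[2] < 0:
            mean = -mean
        means.append(mean)
        ang = np.arccos(np.clip(np.abs(members @ mean), 0.0, 1.0))
        ok = ang <= outlier_angle
        idx = np.where(raw == c)[0]
        labels[idx[ok]] = len(means)
    means = np.asarray(means)
    counts = np.array([(labels == c + 1).sum() for c in range(len(means))])
    return OrientationClustering(folded=folded, labels=labels, means=means,
                                 counts=counts, fractions=counts / n, n=n)


def classify_cube_outcome(omega_or_c2) -> str:
    """Classify a cube-array orientation as transverse / longitudinal / other.

    Accepts either the director (unit vector; z is the cube axis) or the C2
    value directly.  Thresholds: C2 > 0.5 -> transverse, C2 < -0.25 ->
    longitudinal, otherwise other.
    """
    if np.isscalar(omega_or_c2):
        c2 = float(omega_or_c2)
    else:
        c2 = c2_from_omega(np.asarray(omega_or_c2, dtype=float))
    if c2 > C2_TRANSVERSE_THRESHOLD:
        return "transverse"
    if c2 < C2_LONGITUDINAL_THRESHOLD:
        return "longitudinal"
    return "other"


def wilson_interval(successes: int, n: int, alpha: float = 0.05
                    ) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial fraction."""
    from statsmodels.stats.proportion import proportion_confint
    lo, hi = proportion_confint(successes, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def lambert_equal_area(folded: np.ndarray) -> np.ndarray:
    """Lambert azimuthal equal-area projection of the z>=0 hemisphere to a disc."""
    folded = np.atleast_2d(folded)
    z = np.clip(folded[:, 2], 0.0, 1.0)
    f = np.sqrt(2.0 / np.clip(1.0 + z, 1e-12, None))
    return folded[:, :2] * f[:, None]


def isotropy_test(omegas: np.ndarray, n_bins: int = 16
                  ) -> tuple[float, float, int]:
    """Chi-squared test of uniformity of folded director tips on the sphere.

    The folded tips are mapped by the Lambert equal-area projection to a disc
    and binned into equal-area cells (radial rings x angular sectors); under
    isotropy every cell has the same expected count.  Bins are coarsened when
    the expected count per cell falls below 5.

    Returns (chi2 statistic, p-value, number of cells used).
    """
    folded = fold_directors(omegas)
    n = len(folded)
    cells = int(n_bins)
    while cells > 2 and n / cells < 5:
        cells //= 2
    cells = max(cells, 2)
    n_r = max(1, int(round(math.sqrt(cells / 4.0))))
    n_phi = max(2, cells // n_r)
    xy = lambert_equal_area(folded)
    R = math.sqrt(2.0)
    r = np.minimum(np.linalg.norm(xy, axis=1), R - 1e-12)
    phi = np.mod(np.arctan2(xy[:, 1], xy[:, 0]), 2 * math.pi)
    # equal-area radial ring boundaries: r_k = R sqrt(k / n_r)
    ring = np.minimum((n_r * (r / R) ** 2).astype(int), n_r - 1)
    sector = np.minimum((n_phi * phi / (2 * math.pi)).astype(int), n_phi - 1)
    counts = np.zeros(n_r * n_phi)
    np.add.at(counts, ring * n_phi + sector, 1)
    stat, p = chisquare(counts)
    return float(stat), float(p), int(n_r * n_phi)


def scan_parameter(surface: TriangulatedSurface, params: SimulationParameters,
                   axis: str, values, n: int, base_seed: int = 0,
                   classify: bool = True) -> pd.DataFrame:
    """Independent ensembles along one parameter axis.

    ``axis`` may be a plain SimulationParameters field or an edge-class
    probability written as ``"edge:<class>"`` (e.g. ``"edge:transverse"``).
    Returns one row per value with mean Q2, outcome fractions and Wilson 95%
    intervals.
    """
    rows = []
    for i, value in enumerate(values):
        if axis.startswith("edge:"):
            cls = axis.split(":", 1)[1]
            em = params.edge_model
            probs = dict(em.class_probabilities)
            probs[cls] = float(value)
            p = params.with_overrides(
                edge_model=type(em)(kind=em.kind,
                                    class_probabilities=probs,
                                    e_cat=em.e_cat))
        elif hasattr(params, axis):
            p = params.with_overrides(**{axis: value})
        else:
            raise ValueError(f"unknown parameter {axis!r}")
        ens = run_ensemble(surface, p, n=n, base_seed=base_seed + 100000 * i)
        row = {"value": value, "n": n,
               "mean_Q2": float(np.nanmean(ens.Q2))}
        if classify:
            outcomes = [classify_cube_outcome(c2) for c2 in ens.table["C2"]]
            for cls in ("transverse", "longitudinal", "other"):
                cnt = outcomes.count(cls)
                lo, hi = wilson_interval(cnt, n)
                row[f"frac_{cls}"] = cnt / n
                row[f"ci_{cls}_lo"] = lo
                row[f"ci_{cls}_hi"] = hi
        rows.append(row)
    return pd.DataFrame(rows)
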