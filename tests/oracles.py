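"""Independent reference implementations used to validate the package.

These oracles deliberately avoid the code paths they check: the RMSD
oracle minimizes over rotation parameterizations numerically instead of
using the closed-form SVD solution, and the clustering oracle is a plain
dict/set re-implementation of the greedy neighbor-count procedure.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def _fibonacci_axes(n: int) -> np.ndarray:
    """n roughly uniform unit vectors (deterministic)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = math.pi * (1 + 5**0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def oracle_min_rmsd(mobile: np.ndarray, fixed: np.ndarray) -> float:
    """Minimum RMSD over proper rigid motions by numerical optimization.

    Translations are removed by centering (the optimum superposes the
    centroids); the rotation is found by multi-start quasi-Newton
    minimization over rotation vectors.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(fixed, float)
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    n = P.shape[0]

    def objective(rv: np.ndarray) -> float:
        R = Rotation.from_rotvec(rv).as_matrix()
        diff = P @ R.T - Q
        return float(np.sum(diff * diff) / n)

    starts = [np.zeros(3)]
    for angle in (0.9, 1.8, 2.7):
        for axis in _fibonacci_axes(6):
            starts.append(angle * axis)
    best_fun = math.inf
    best_x = np.zeros(3)
    for x0 in starts:
        res = minimize(objective, x0, method="BFGS", options={"gtol": 1e-14})
        if res.fun < best_fun:
            best_fun = float(res.fun)
            best_x = res.x
    # polish the winning basin for the last digits
    res = minimize(
        objective, best_x, method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 2000},
    )
    best_fun = min(best_fun, float(res.fun))
    return math.sqrt(max(best_fun, 0.0))


def _id_rank(model_id: str) -> int:
    tail = model_id.rpartition("#")[2]
    return int(tail) if tail.isdigit() else 0


def oracle_greedy_clusters(
    ids: list[str], values: np.ndarray, cutoff: float
) -> list[tuple[str, list[str]]]:
    """Greedy neighbor-count clustering, re-implemented with dicts/sets.

    Returns ``[(medoid, members_in_order), ...]`` in extraction order,
    members medoid-first then by distance (ties by id); medoid ties break
    by (rank, id).
    """
    n = len(ids)
    neighbors = {
        i: {j for j in range(n) if j != i and values[i][j] < cutoff}
        for i in range(n)
    }
    unassigned = set(range(n))
    clusters = []
    while unassigned:
        def count(i: int) -> int:
            return len(neighbors[i] & unassigned)

        best = max(unassigned, key=lambda i: (count(i), ))
        candidates = [i for i in unassigned if count(i) == count(best)]
        medoid = min(candidates, key=lambda i: (_id_rank(ids[i]), ids[i]))
        members = sorted(
            neighbors[medoid] & unassigned,
            key=lambda j: (values[medoid][j], ids[j]),
        )
        clusters.append((ids[medoid], [ids[medoid]] + [ids[j] for j in members]))
        unassigned -= {medoid} | (neighbors[medoid] & unassigned)
    return clusters


def oracle_autocluster_cutoff(
    ids: list[str],
    values: np.ndarray,
    mode: str,
    start: float = 0.5,
    step: float = 0.5,
    max_cutoff: float = 50.0,
) -> float | None:
    """Smallest grid cutoff meeting the stopping criterion (grid scan)."""
    n = len(ids)
    k = 0
    while True:
        cutoff = start + k * step
        if cutoff > max_cutoff + 1e-9:
            return None
        sizes = [len(members) for _, members in
                 oracle_greedy_clusters(ids, values, cutoff)]
        if mode == "one_of_six":
            ok = sizes[0] > n / 6
        else:
            ok = sum(sizes[:3]) >= math.ceil(n / 2)
        if ok:
            return cutoff
        k += 1
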