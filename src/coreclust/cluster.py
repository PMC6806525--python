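"""Neighbor-count clustering of decoy ensembles.

The procedure follows the classic decoy-clustering scheme used in
fragment-assembly structure prediction: two structures are neighbors when
their (core) RMSD is strictly below a distance cutoff; clusters are
extracted greedily by repeatedly taking the unassigned structure with the
most unassigned neighbors as a medoid, together with those neighbors.

Because the right cutoff depends on ensemble diversity, an iterative
search starts at 0.5 Å and increases in 0.5 Å steps until a stopping
criterion is met:

* ``one_of_six`` — the first (biggest) cluster holds over 1/6 of all
  structures (for 500 structures: more than 83);
* ``half`` — the first three clusters together hold at least half
  (ceil(n/2); for 500 structures: at least 250).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ClusteringError
from .geometry import DistanceMatrix
from .structures import rank_from_id

MODES = ("one_of_six", "half", "fixed")


@dataclass(frozen=True)
class Cluster:
    medoid: str
    members: tuple[str, ...]  # medoid first, then by distance to medoid

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ClusterResult:
    """Clusters at one cutoff, in extraction order (first = biggest then)."""

    cutoff: float
    clusters: tuple[Cluster, ...]
    mode: str = "fixed"

    @property
    def n(self) -> int:
        return sum(len(c) for c in self.clusters)

    def sizes(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.clusters)

    def labels(self) -> dict[str, int]:
        """model_id → 0-based cluster index (for partition comparisons)."""
        return {
            mid: k for k, cl in enumerate(self.clusters) for mid in cl.members
        }

    def to_text(self, path: str | Path) -> None:
        lines = [f"# mode={self.mode}"]
        for k, cl in enumerate(self.clusters, start=1):
            lines.append(
                f"cluster{k} cutoff={self.cutoff:.2f} medoid={cl.medoid} "
                f"n={len(cl)} members={' '.join(cl.members)}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "ClusterResult":
        mode = "fixed"
        cutoff = 0.0
        clusters = []
        for ln in Path(path).read_text().splitlines():
            ln = ln.strip()
            if not ln:
                continue
            if ln.startswith("#"):
                if "mode=" in ln:
                    mode = ln.split("mode=")[1].split()[0]
                continue
            fields = dict(
                kv.split("=", 1) for kv in ln.split(" ", 4)[1:] if "=" in kv
            )
            cutoff = float(fields["cutoff"])
            members = tuple(fields["members"].split())
            clusters.append(Cluster(medoid=fields["medoid"], members=members))
        if not clusters:
            raise ClusteringError(f"no clusters found in {path}")
        return cls(cutoff=cutoff, clusters=tuple(clusters), mode=mode)


def neighbor_counts(matrix: DistanceMatrix, cutoff: float) -> dict[str, int]:
    """Per-model count of other models at distance strictly below cutoff."""
    if cutoff <= 0:
        raise ClusteringError(f"cutoff must be > 0, got {cutoff}")
    adj = matrix.values < cutoff
    np.fill_diagonal(adj, False)
    counts = adj.sum(axis=1)
    return {mid: int(c) for mid, c in zip(matrix.ids, counts)}


def _ranks(matrix: DistanceMatrix, ranks: Mapping[str, int] | None) -> np.ndarray:
    if ranks is None:
        return np.array([rank_from_id(mid) for mid in matrix.ids])
    return np.array([ranks.get(mid, 0) for mid in matrix.ids])


def cluster_at(
    matrix: DistanceMatrix,
    cutoff: float,
    ranks: Mapping[str, int] | None = None,
    mode: str = "fixed",
) -> ClusterResult:
    """Greedy neighbor-count clustering at a fixed cutoff.

    Repeatedly the unassigned model with the most unassigned neighbors
    becomes a medoid (ties broken by lower energy rank, then lexicographic
    id); its cluster is the medoid plus its unassigned neighbors, listed
    medoid-first then by increasing distance to the medoid. Models without
    neighbors end up as singleton clusters.
    """
    if cutoff <= 0:
        raise ClusteringError(f"cutoff must be > 0, got {cutoff}")
    n = len(matrix)
    if n == 0:
        raise ClusteringError("cannot cluster an empty distance matrix")
    adj = matrix.values < cutoff
    np.fill_diagonal(adj, False)
    rank_arr = _ranks(matrix, ranks)
    ids = matrix.ids

    alive = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while alive.any():
        counts = (adj & alive[None, :]).sum(axis=1)
        counts[~alive] = -1
        best_count = counts.max()
        cand = np.flatnonzero(counts == best_count)
        medoid_idx = min(cand, key=lambda i: (rank_arr[i], ids[i]))
        member_idx = np.flatnonzero(adj[medoid_idx] & alive)
        member_idx = sorted(
            member_idx, key=lambda j: (matrix.values[medoid_idx, j], ids[j])
        )
        members = (ids[medoid_idx],) + tuple(ids[j] for j in member_idx)
        clusters.append(Cluster(medoid=ids[medoid_idx], members=members))
        alive[medoid_idx] = False
        alive[list(member_idx)] = False
    return ClusterResult(cutoff=cutoff, clusters=tuple(clusters), mode=mode)


def criterion_met(result: ClusterResult, mode: str, n: int) -> bool:
    """Check a stopping criterion.

    ``one_of_six`` requires the first cluster to hold strictly more than
    n/6 structures (for 500 inputs: over 83, i.e. at least 84); ``half``
    requires the first three clusters to hold at least ceil(n/2)
    (for 500: at least 250).
    """
    sizes = result.sizes()
    if mode == "one_of_six":
        return sizes[0] > n / 6
    if mode == "half":
        return sum(sizes[:3]) >= math.ceil(n / 2)
    raise ClusteringError(f"unknown autocluster mode '{mode}'")


def autocluster(
    matrix: DistanceMatrix,
    mode: str = "one_of_six",
    start: float = 0.5,
    step: float = 0.5,
    max_cutoff: float = 50.0,
    ranks: Mapping[str, int] | None = None,
) -> ClusterResult:
    """Iterative cutoff search: smallest grid cutoff meeting the criterion.

    The grid is ``start, start+step, ...`` up to ``max_cutoff``; clustering
    is re-run at each cutoff until the requested criterion first holds.
    """
    if mode not in ("one_of_six", "half"):
        raise ClusteringError(
            f"autocluster mode must be 'one_of_six' or 'half', got '{mode}'"
        )
    if start <= 0 or step <= 0:
        raise ClusteringError("start and step cutoffs must be > 0")
    n = len(matrix)
    trajectory: list[tuple[float, int]] = []
    k = 0
    while True:
        cutoff = start + k * step
        if cutoff > max_cutoff + 1e-9:
            break
        result = cluster_at(matrix, cutoff, ranks=ranks, mode=mode)
        if criterion_met(result, mode, n):
            return result
        trajectory.append((cutoff, result.sizes()[0]))
        k += 1
    traj = ", ".join(f"{c:.2f}Å→{s}" for c, s in trajectory)
    raise ClusteringError(
        f"'{mode}' criterion not met up to {max_cutoff} Å; "
        f"first-cluster sizes along the way: {traj}"
    )
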