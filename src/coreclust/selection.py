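"""Final model selection for the target sequence.

Two published rules are supported:

* ``cluster_scan`` (default) — scan clusters in extraction order and,
  within each cluster, members in order; the first model belonging to the
  target sequence is the prediction. If the first cluster holds no target
  model the second is processed, and so on.
* ``max_neighbors`` — the target model with the highest neighbor count at
  the terminating cutoff (ties broken by lower energy rank).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .cluster import ClusterResult, neighbor_counts
from .errors import SelectionError
from .geometry import DistanceMatrix
from .structures import ModelSet, rank_from_id

RULES = ("cluster_scan", "max_neighbors")


@dataclass(frozen=True)
class SelectionReport:
    chosen: str
    cluster_index: int  # 1-based index of the cluster containing chosen
    rule: str
    runner_ups: tuple[str, ...]

    def to_text(self, path: str | Path) -> None:
        lines = [
            f"chosen={self.chosen}",
            f"cluster_index={self.cluster_index}",
            f"rule={self.rule}",
            f"runner_ups={' '.join(self.runner_ups)}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def _homolog_map(models: ModelSet | Mapping[str, str]) -> Mapping[str, str]:
    return models.homolog_by_id() if isinstance(models, ModelSet) else models


def select_final(
    clusters: ClusterResult,
    models: ModelSet | Mapping[str, str],
    target: str | None = None,
    rule: str = "cluster_scan",
    matrix: DistanceMatrix | None = None,
    ranks: Mapping[str, int] | None = None,
) -> SelectionReport:
    """Pick the final model for the target sequence from a clustering.

    ``models`` may be a ModelSet (target defaults to its target_name) or a
    plain ``model_id → homolog`` mapping with an explicit ``target``.
    ``matrix`` is required for the ``max_neighbors`` rule, whose neighbor
    counts are evaluated at the clustering's terminating cutoff.
    """
    if rule not in RULES:
        raise SelectionError(f"unknown selection rule '{rule}'")
    homolog_of = _homolog_map(models)
    if target is None:
        if not isinstance(models, ModelSet):
            raise SelectionError("target must be given with a plain homolog map")
        target = models.target_name

    # target models in cluster-scan order, with their 1-based cluster index
    scan: list[tuple[str, int]] = []
    for k, cl in enumerate(clusters.clusters, start=1):
        for mid in cl.members:
            if homolog_of.get(mid) == target:
                scan.append((mid, k))
    if not scan:
        raise SelectionError(
            f"no model of target '{target}' appears in any cluster"
        )

    if rule == "cluster_scan":
        chosen, cluster_index = scan[0]
        runner_ups = tuple(mid for mid, _ in scan[1:])
    else:  # max_neighbors
        if matrix is None:
            raise SelectionError("max_neighbors rule requires the distance matrix")
        counts = neighbor_counts(matrix, clusters.cutoff)
        rank_of = (
            models.rank_by_id()
            if isinstance(models, ModelSet)
            else {mid: rank_from_id(mid) for mid, _ in scan}
        )
        if ranks is not None:
            rank_of = dict(ranks)
        ordered = sorted(
            (mid for mid, _ in scan),
            key=lambda mid: (-counts.get(mid, 0), rank_of.get(mid, 0), mid),
        )
        chosen = ordered[0]
        cluster_index = next(k for mid, k in scan if mid == chosen)
        runner_ups = tuple(ordered[1:])
    return SelectionReport(
        chosen=chosen, cluster_index=cluster_index, rule=rule, runner_ups=runner_ups
    )
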