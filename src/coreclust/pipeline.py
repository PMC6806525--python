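"""End-to-end driver: alignment → core → matrix → clusters → final model.

``analyze`` runs the consensus machinery on in-memory objects;
``run_pipeline`` is the file-based wrapper that the command-line
interface calls, writing every intermediate artifact for provenance.
"""

from __future__ import annotations

import dataclasses
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

from . import clans as clans_mod
from .cluster import ClusterResult, autocluster, cluster_at
from .errors import CoreclustError
from .evaluation import EvalReport, evaluate
from .geometry import CoreTrace, DistanceMatrix, all_vs_all, traces_for
from .msa import Alignment, CoreMap, conserved_core, read_alignment, reduce_redundancy
from .selection import SelectionReport, select_final
from .structures import ModelSet, load_model_set, read_pdb, write_pdb

logger = logging.getLogger("coreclust")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    alignment: Path
    models_dir: Path
    mapping: Path
    out_dir: Path
    target: str | None = None
    alignment_format: str = "fasta"
    identity_threshold: float | None = None  # optional redundancy reduction
    per_homolog_limit: int = 100
    mode: str = "one_of_six"  # or "half"
    rule: str = "cluster_scan"  # or "max_neighbors"
    start: float = 0.5
    step: float = 0.5
    max_cutoff: float = 50.0
    reference: Path | None = None
    reference_ss: Path | None = None
    clans_threshold: float | None = None
    log_level: str = "INFO"

    def echo(self, path: Path) -> None:
        lines = [
            f"{f.name}={getattr(self, f.name)}"
            for f in dataclasses.fields(self)
        ]
        path.write_text("\n".join(lines) + "\n")


class AnalysisResult(NamedTuple):
    core: CoreMap
    traces: list[CoreTrace]
    matrix: DistanceMatrix
    clusters: ClusterResult
    selection: SelectionReport


def analyze(
    alignment: Alignment,
    model_set: ModelSet,
    mode: str = "one_of_six",
    rule: str = "cluster_scan",
    start: float = 0.5,
    step: float = 0.5,
    max_cutoff: float = 50.0,
    selected: list[str] | None = None,
) -> AnalysisResult:
    """Core → all-vs-all matrix → iterative clustering → selection."""
    selected = selected if selected is not None else list(model_set.homologs)
    core = conserved_core(alignment, selected)
    logger.info("conserved core: %d columns", core.size)
    traces = traces_for(model_set, core)
    matrix = all_vs_all(traces)
    logger.info("distance matrix: %d models", len(matrix))
    clusters = autocluster(
        matrix,
        mode=mode,
        start=start,
        step=step,
        max_cutoff=max_cutoff,
        ranks=model_set.rank_by_id(),
    )
    logger.info(
        "clustering terminated at %.2f Å with cluster sizes %s",
        clusters.cutoff,
        list(clusters.sizes()[:5]),
    )
    selection = select_final(
        clusters, model_set, rule=rule, matrix=matrix, ranks=model_set.rank_by_id()
    )
    logger.info(
        "selected %s from cluster %d (%s rule)",
        selection.chosen,
        selection.cluster_index,
        selection.rule,
    )
    return AnalysisResult(core, traces, matrix, clusters, selection)


def run_pipeline(config: RunConfig) -> AnalysisResult:
    """File-based pipeline run; writes all artifacts into the output dir.

    Artifacts: ``run_config.txt``, ``core_map.tsv``,
    ``distance_matrix.txt``, ``clusters.txt``, ``selection.txt``, the
    chosen model PDB, and optionally ``evaluation.txt`` and
    ``clusters.clans``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level.upper())
    try:
        config.echo(out / "run_config.txt")
        alignment = read_alignment(config.alignment, config.alignment_format)
        if config.identity_threshold is not None:
            before = len(alignment)
            alignment = reduce_redundancy(alignment, config.identity_threshold)
            logger.info("redundancy reduction kept %d of %d", len(alignment), before)
        model_set = load_model_set(
            config.models_dir,
            config.mapping,
            per_homolog_limit=config.per_homolog_limit,
            target_name=config.target,
        )
        result = analyze(
            alignment,
            model_set,
            mode=config.mode,
            rule=config.rule,
            start=config.start,
            step=config.step,
            max_cutoff=config.max_cutoff,
        )

        result.core.to_tsv(out / "core_map.tsv")
        result.matrix.write_text(out / "distance_matrix.txt")
        result.clusters.to_text(out / "clusters.txt")
        result.selection.to_text(out / "selection.txt")
        chosen = model_set.by_id(result.selection.chosen)
        chosen_path = out / "chosen_model.pdb"
        if chosen.source is not None:
            shutil.copyfile(chosen.source, chosen_path)
        else:
            write_pdb(chosen, chosen_path)

        if config.reference is not None:
            ref = read_pdb(
                config.reference,
                model_id="reference",
                homolog=model_set.target_name,
            )
            ref_ss = (
                Path(config.reference_ss).read_text().strip()
                if config.reference_ss
                else None
            )
            report = evaluate(chosen, ref, result.core, ref_ss=ref_ss)
            (out / "evaluation.txt").write_text("\n".join(report.to_lines()) + "\n")
            logger.info("evaluation: %s", "; ".join(report.to_lines()))

        if config.clans_threshold is not None:
            doc = clans_mod.to_clans(
                result.matrix,
                model_set.homolog_by_id(),
                threshold=config.clans_threshold,
                target=model_set.target_name,
                traces=result.traces,
            )
            clans_mod.write_clans(doc, out / "clusters.clans")
        return result
    finally:
        logger.removeHandler(handler)
        handler.close()
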