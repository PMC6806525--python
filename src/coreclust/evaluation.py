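"""Model accuracy: RMSD, core RMSD, and Interaction Network Fidelity.

INF is the geometric mean of precision and recall over sets of base-base
interactions::

    INF = sqrt( TP/(TP+FP) * TP/(TP+FN) )

where TP are interactions shared by prediction and reference, FP are
predicted-only and FN reference-only. INF is undefined (reported as None,
never coerced to 0) when either denominator vanishes.

Interaction sets can come from three sources: user-supplied dot-bracket
strings, externally computed interaction lists (TSV), or a minimal
geometric detector. The detector uses simple distance/angle thresholds on
idealized coordinates; it is a documented, configurable heuristic and does
not attempt to reproduce a full contact classifier.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .errors import EvaluationError
from .geometry import core_rmsd, core_trace, rmsd_heavy
from .msa import CoreMap
from .structures import StructureModel

logger = logging.getLogger(__name__)

BASE_PAIR = "base_pair"
STACKING = "stacking"

#: Watson–Crick edge donor/acceptor atom names (purines and pyrimidines).
WC_EDGE_ATOMS = ("N1", "C2", "N3", "N4", "O2", "O4", "N6", "O6")
#: Ring/base atoms used for base centroids and plane normals.
BASE_ATOMS = (
    "N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9",
    "O2", "N4", "O4", "N6", "O6",
)

Pair = tuple[int, int, str]


@dataclass(frozen=True)
class InteractionSet:
    """Canonical set of residue-residue interactions (0-based, i < j)."""

    pairs: frozenset[Pair]

    @classmethod
    def from_pairs(cls, pairs) -> "InteractionSet":
        canon = set()
        for i, j, kind in pairs:
            if i == j:
                raise EvaluationError(f"self-interaction ({i}, {j}) is not allowed")
            lo, hi = (i, j) if i < j else (j, i)
            canon.add((lo, hi, kind))
        return cls(frozenset(canon))

    def of_kind(self, kind: str) -> "InteractionSet":
        return InteractionSet(frozenset(p for p in self.pairs if p[2] == kind))

    def __len__(self) -> int:
        return len(self.pairs)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{i}\t{j}\t{kind}" for i, j, kind in sorted(self.pairs)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InteractionSet":
        pairs = []
        for lineno, ln in enumerate(Path(path).read_text().splitlines(), 1):
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            fields = ln.split("\t")
            if len(fields) != 3:
                raise EvaluationError(
                    f"{path}:{lineno}: expected 'i<TAB>j<TAB>kind'"
                )
            pairs.append((int(fields[0]), int(fields[1]), fields[2]))
        return cls.from_pairs(pairs)


class InfResult(NamedTuple):
    inf: float | None  # None when undefined (zero denominator)
    tp: int
    fp: int
    fn: int


def inf(pred: InteractionSet, ref: InteractionSet) -> InfResult:
    """Interaction Network Fidelity between two interaction sets."""
    tp = len(pred.pairs & ref.pairs)
    fp = len(pred.pairs - ref.pairs)
    fn = len(ref.pairs - pred.pairs)
    if tp + fp == 0 or tp + fn == 0:
        return InfResult(None, tp, fp, fn)
    value = math.sqrt((tp / (tp + fp)) * (tp / (tp + fn)))
    return InfResult(value, tp, fp, fn)


_OPENERS = {"(": ")", "[": "]", "{": "}"}
_CLOSERS = {v: k for k, v in _OPENERS.items()}


def parse_dotbracket(ss: str) -> InteractionSet:
    """Base pairs from a dot-bracket string; (), [] and {} are independent
    pseudoknot layers; '.' is unpaired."""
    stacks: dict[str, list[int]] = {b: [] for b in _OPENERS}
    pairs = []
    for pos, ch in enumerate(ss.strip()):
        if ch == ".":
            continue
        if ch in _OPENERS:
            stacks[ch].append(pos)
        elif ch in _CLOSERS:
            opener = _CLOSERS[ch]
            if not stacks[opener]:
                raise EvaluationError(
                    f"unbalanced '{ch}' at position {pos} in dot-bracket string"
                )
            pairs.append((stacks[opener].pop(), pos, BASE_PAIR))
        else:
            raise EvaluationError(
                f"unexpected character '{ch}' at position {pos} in dot-bracket string"
            )
    for opener, stack in stacks.items():
        if stack:
            raise EvaluationError(
                f"unbalanced '{opener}' at position {stack[-1]} in dot-bracket string"
            )
    return InteractionSet.from_pairs(pairs)


def _base_geometry(res) -> tuple[np.ndarray, np.ndarray] | None:
    """(centroid, unit plane normal) of a residue's base atoms, or None."""
    coords = np.array([res.atoms[a] for a in BASE_ATOMS if a in res.atoms])
    if coords.shape[0] < 3:
        return None
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, sv, vt = np.linalg.svd(centered)
    if sv[1] <= 1e-8:  # collinear base atoms, no plane
        return None
    return centroid, vt[2]


def detect_interactions(
    model: StructureModel,
    bp_c1_range: tuple[float, float] = (8.0, 12.0),
    wc_cutoff: float = 3.5,
    stack_centroid_cutoff: float = 5.5,
    stack_angle_cutoff: float = 30.0,
) -> InteractionSet:
    """Minimal geometric interaction detector.

    Base pairs: residue pairs whose C1'-C1' distance lies in
    ``bp_c1_range`` and whose closest Watson–Crick-edge donor/acceptor
    atom pair is below ``wc_cutoff`` Å. Stacking: sequence-nonadjacent
    pairs with base-centroid distance below ``stack_centroid_cutoff`` Å
    and base-plane normals within ``stack_angle_cutoff`` degrees.
    """
    n = len(model.residues)
    c1 = []
    wc = []
    geom = []
    for idx, res in enumerate(model.residues):
        c1.append(res.atoms.get("C1'"))
        wc_atoms = np.array(
            [res.atoms[a] for a in WC_EDGE_ATOMS if a in res.atoms]
        )
        wc.append(wc_atoms if wc_atoms.size else None)
        g = _base_geometry(res)
        if g is None:
            logger.warning(
                "model %s: residue %d (%s) lacks base atoms; skipped in "
                "interaction detection", model.model_id, idx + 1, res.res_name,
            )
        geom.append(g)

    pairs = []
    cos_cut = math.cos(math.radians(stack_angle_cutoff))
    for i in range(n):
        for j in range(i + 1, n):
            if c1[i] is not None and c1[j] is not None and wc[i] is not None and wc[j] is not None:
                d = float(np.linalg.norm(c1[i] - c1[j]))
                if bp_c1_range[0] <= d <= bp_c1_range[1]:
                    diff = wc[i][:, None, :] - wc[j][None, :, :]
                    min_wc = float(np.sqrt((diff ** 2).sum(axis=2).min()))
                    if min_wc < wc_cutoff:
                        pairs.append((i, j, BASE_PAIR))
            if j - i > 1 and geom[i] is not None and geom[j] is not None:
                ci, ni = geom[i]
                cj, nj = geom[j]
                if float(np.linalg.norm(ci - cj)) < stack_centroid_cutoff:
                    if abs(float(ni @ nj)) >= cos_cut:
                        pairs.append((i, j, STACKING))
    return InteractionSet.from_pairs(pairs)


@dataclass(frozen=True)
class EvalReport:
    """Accuracy of one prediction against a reference structure."""

    core_rmsd: float
    rmsd_heavy: float | None = None
    inf_all: float | None = None
    inf_bp: float | None = None
    inf_stack: float | None = None
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @staticmethod
    def _fmt(x: float | None) -> str:
        return "NA" if x is None else f"{x:.4f}"

    def to_lines(self) -> list[str]:
        return [
            f"core_rmsd={self.core_rmsd:.4f}",
            f"rmsd_heavy={self._fmt(self.rmsd_heavy)}",
            f"inf_all={self._fmt(self.inf_all)}",
            f"inf_bp={self._fmt(self.inf_bp)}",
            f"inf_stack={self._fmt(self.inf_stack)}",
            f"tp={self.tp}",
            f"fp={self.fp}",
            f"fn={self.fn}",
        ]

    def to_csv_row(self, model_id: str) -> str:
        return ",".join(
            [model_id, f"{self.core_rmsd:.4f}", self._fmt(self.rmsd_heavy),
             self._fmt(self.inf_all), self._fmt(self.inf_bp),
             self._fmt(self.inf_stack), str(self.tp), str(self.fp), str(self.fn)]
        )

    CSV_HEADER = "model_id,core_rmsd,rmsd_heavy,inf_all,inf_bp,inf_stack,tp,fp,fn"


def evaluate(
    pred: StructureModel,
    ref: StructureModel,
    core: CoreMap,
    pred_ss: str | None = None,
    ref_ss: str | None = None,
    pred_interactions: InteractionSet | None = None,
    ref_interactions: InteractionSet | None = None,
) -> EvalReport:
    """Score a prediction against the reference structure.

    Core RMSD is always computed (both models must map into the core).
    Heavy-atom RMSD is computed only when residue counts match. INF uses,
    in order of precedence, explicit interaction sets, dot-bracket
    strings, or the geometric detector applied to both structures.
    """
    cr = core_rmsd(core_trace(pred, core), core_trace(ref, core))

    rh: float | None = None
    if len(pred) == len(ref):
        rh = rmsd_heavy(pred, ref)

    if pred_interactions is None:
        pred_interactions = (
            parse_dotbracket(pred_ss) if pred_ss is not None
            else detect_interactions(pred)
        )
    if ref_interactions is None:
        ref_interactions = (
            parse_dotbracket(ref_ss) if ref_ss is not None
            else detect_interactions(ref)
        )

    all_res = inf(pred_interactions, ref_interactions)
    bp_res = inf(pred_interactions.of_kind(BASE_PAIR), ref_interactions.of_kind(BASE_PAIR))
    st_res = inf(pred_interactions.of_kind(STACKING), ref_interactions.of_kind(STACKING))
    return EvalReport(
        core_rmsd=cr,
        rmsd_heavy=rh,
        inf_all=all_res.inf,
        inf_bp=bp_res.inf,
        inf_stack=st_res.inf,
        tp=all_res.tp,
        fp=all_res.fp,
        fn=all_res.fn,
    )
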