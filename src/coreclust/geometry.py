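"""Rigid-body superposition and the RMSD family.

Three metrics are provided:

* ``superpose`` — optimal proper rigid superposition (covariance SVD with
  determinant sign correction) of two equally sized point sets, returning
  the minimizing rotation, translation and RMSD
  ``sqrt((1/N) * sum_i |delta_i|^2)``.
* ``rmsd_heavy`` — all-heavy-atom RMSD between two models of the same
  length, pairing atoms by name intersection per residue.
* ``core_rmsd`` / ``all_vs_all`` — RMSD over only the C3' atoms of the
  conserved core, the cross-homolog metric that drives clustering. Cores
  have the same length for every homolog by construction, so traces of
  models with different sequence lengths are always comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import GeometryError, StructureError
from .msa import CoreMap
from .structures import C3_PRIME, ModelSet, StructureModel, is_hydrogen

_PAIR_CHUNK = 20_000  # pairs per SVD batch in all_vs_all


def _kabsch_terms(P: np.ndarray, Q: np.ndarray):
    """Centered arrays, centroids and the covariance SVD of one pair."""
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = 1.0 if np.linalg.det(U @ Vt) >= 0 else -1.0
    return P0, Q0, pc, qc, U, S, Vt, d


def _min_rmsd(P0: np.ndarray, Q0: np.ndarray, S: np.ndarray, d: float) -> float:
    n = P0.shape[0]
    msd = (np.sum(P0 * P0) + np.sum(Q0 * Q0) - 2.0 * (S[0] + S[1] + d * S[2])) / n
    return float(np.sqrt(max(msd, 0.0)))


def superpose(
    mobile: Sequence[Sequence[float]] | np.ndarray,
    fixed: Sequence[Sequence[float]] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rigid superposition of ``mobile`` onto ``fixed``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ p + translation`` maps mobile points onto the fixed frame
    with the global minimum RMSD over all proper rigid motions
    (reflections are excluded via the determinant sign correction).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(fixed, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError(
            f"point sets must both be (N, 3) with equal N; got {P.shape} vs {Q.shape}"
        )
    if P.shape[0] < 3:
        raise GeometryError("superposition needs at least 3 points")
    for name, X in (("mobile", P), ("fixed", Q)):
        sv = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
        if sv[1] <= 1e-8 * max(sv[0], 1.0):
            raise GeometryError(f"{name} point set is degenerate (collinear)")
    P0, Q0, pc, qc, U, S, Vt, d = _kabsch_terms(P, Q)
    D = np.diag([1.0, 1.0, d])
    rotation = Vt.T @ D @ U.T
    translation = qc - rotation @ pc
    return rotation, translation, _min_rmsd(P0, Q0, S, d)


def kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimum RMSD only (no degeneracy guard; used on core traces)."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise GeometryError(f"point count mismatch: {P.shape} vs {Q.shape}")
    P0, Q0, _, _, _, S, _, d = _kabsch_terms(P, Q)
    return _min_rmsd(P0, Q0, S, d)


def rmsd_heavy(model: StructureModel, reference: StructureModel) -> float:
    """All-heavy-atom RMSD after optimal superposition.

    Only meaningful for models of the same sequence (equal residue
    counts); per residue, atoms are paired by the intersection of their
    non-hydrogen atom names, tolerating decoys with incomplete atom sets.
    """
    if len(model) != len(reference):
        raise GeometryError(
            "heavy-atom RMSD needs equal residue counts "
            f"({len(model)} vs {len(reference)}); use core_rmsd across homologs"
        )
    mob, fix = [], []
    for rm, rr in zip(model.residues, reference.residues):
        shared = sorted(
            name
            for name in set(rm.atoms) & set(rr.atoms)
            if not is_hydrogen(name)
        )
        for name in shared:
            mob.append(rm.atoms[name])
            fix.append(rr.atoms[name])
    if len(mob) < 3:
        raise GeometryError("fewer than 3 shared heavy atoms between models")
    _, _, value = superpose(np.array(mob), np.array(fix))
    return value


@dataclass(frozen=True)
class CoreTrace:
    """Ordered C3' coordinates of one model's conserved-core residues."""

    model_id: str
    points: np.ndarray  # (n_core, 3)


def core_trace(model: StructureModel, core: CoreMap) -> CoreTrace:
    """Extract the C3' coordinate of each core residue of a model."""
    if model.homolog not in core.per_seq:
        raise StructureError(
            f"model {model.model_id}: homolog '{model.homolog}' absent from core map"
        )
    idxs = core.per_seq[model.homolog]
    pts = np.empty((len(idxs), 3))
    for k, (col, ridx) in enumerate(zip(core.columns, idxs)):
        if ridx >= len(model.residues):
            raise StructureError(
                f"model {model.model_id}: core column {col} maps to residue "
                f"{ridx + 1} but the model has only {len(model.residues)} residues"
            )
        res = model.residues[ridx]
        if C3_PRIME not in res.atoms:
            raise StructureError(
                f"model {model.model_id}: core column {col} residue lacks {C3_PRIME}"
            )
        pts[k] = res.atoms[C3_PRIME]
    return CoreTrace(model_id=model.model_id, points=pts)


def core_rmsd(a: CoreTrace, b: CoreTrace) -> float:
    """Core RMSD: minimum RMSD over the single C3' atom per core column."""
    return kabsch_rmsd(a.points, b.points)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric all-vs-all core-RMSD matrix (Å) with model identifiers."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.ids)
        if v.shape != (n, n):
            raise GeometryError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise GeometryError("distance matrix entries must be finite and >= 0")
        if np.any(np.abs(np.diag(v)) > 1e-9) or not np.allclose(v, v.T):
            raise GeometryError("distance matrix must be symmetric with zero diagonal")

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, model_id: str) -> int:
        return self.ids.index(model_id)

    def write_text(self, path: str | Path) -> None:
        """Line 1: ids; then one row of 3-decimal floats per model."""
        lines = [" ".join(self.ids)]
        for row in self.values:
            lines.append(" ".join(f"{x:.3f}" for x in row))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_text(cls, path: str | Path) -> "DistanceMatrix":
        lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
        if not lines:
            raise GeometryError(f"empty distance matrix file: {path}")
        ids = tuple(lines[0].split())
        rows = [[float(x) for x in ln.split()] for ln in lines[1 : len(ids) + 1]]
        values = np.array(rows, dtype=float)
        # symmetrize away the 3-decimal write asymmetry guard (exact here,
        # since writes are symmetric; this only normalizes hand-edited files)
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        return cls(ids=ids, values=values)


def traces_for(models: ModelSet | Iterable[StructureModel], core: CoreMap) -> list[CoreTrace]:
    model_iter = models.models if isinstance(models, ModelSet) else models
    return [core_trace(m, core) for m in model_iter]


def all_vs_all(
    models: ModelSet | Iterable[StructureModel] | Sequence[CoreTrace],
    core: CoreMap | None = None,
) -> DistanceMatrix:
    """All-vs-all core RMSD, computed once per unordered pair.

    Accepts a ModelSet (with a CoreMap) or pre-extracted CoreTraces. The
    pairwise Kabsch problems are solved in batches with vectorized 3x3
    SVDs, which keeps n ≈ 500–1000 ensembles fast on one CPU.
    """
    items = list(models.models) if isinstance(models, ModelSet) else list(models)
    if items and isinstance(items[0], CoreTrace):
        traces = items
    else:
        if core is None:
            raise GeometryError("all_vs_all needs a CoreMap when given models")
        traces = [core_trace(m, core) for m in items]
    if not traces:
        raise GeometryError("all_vs_all called with no models")
    ids = tuple(t.model_id for t in traces)
    X = np.stack([t.points for t in traces]).astype(float)  # (n, N, 3)
    n, n_pts, _ = X.shape
    X = X - X.mean(axis=1, keepdims=True)
    sq = np.einsum("nij,nij->n", X, X)

    values = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    for start in range(0, iu.size, _PAIR_CHUNK):
        ii = iu[start : start + _PAIR_CHUNK]
        jj = ju[start : start + _PAIR_CHUNK]
        H = np.einsum("pki,pkj->pij", X[ii], X[jj])
        U, S, Vt = np.linalg.svd(H)
        d = np.where(np.linalg.det(U @ Vt) >= 0, 1.0, -1.0)
        trace_sum = S[:, 0] + S[:, 1] + d * S[:, 2]
        msd = (sq[ii] + sq[jj] - 2.0 * trace_sum) / n_pts
        rms = np.sqrt(np.maximum(msd, 0.0))
        values[ii, jj] = rms
        values[jj, ii] = rms
    return DistanceMatrix(ids=ids, values=values)
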