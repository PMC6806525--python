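"""Seeded generator of complete decoy-clustering inputs.

The generator emulates the input layout the pipeline consumes — an
alignment over a target plus homologs sharing an ungapped core, one ranked
decoy set per homolog, and a name→files mapping — with a known ground
truth, so every stage is testable without external downloads.

Each homolog's chain is a shared idealized core backbone (an A-form-like
helical hairpin: rise 2.8 Å, twist 32.7°/residue, C3' radius 9.4 Å about
the helix axis, plus an extended/loop linker for unpaired residues) with
homolog-specific insertions spliced in; the insertions are gapped out of
the alignment so the conserved core recovers exactly the planted core
columns. Decoys carry a planted cluster label: cluster 0 keeps the
reference conformation and cluster k displaces everything beyond a hinge
at the core midpoint by a rigid motion of magnitude ``k * between_shift``
(a hinge motion changes the shape, so planted clusters stay separated
after optimal superposition), followed by isotropic per-atom Gaussian
jitter of ``within_sigma``. Decoys are perturbed conformations rather
than physically folded structures: the claims under test concern
clustering and selection, not folding.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .errors import ParameterError
from .msa import Alignment
from .structures import ModelSet, Residue, StructureModel, make_model_id, write_pdb

RISE = 2.8  # Å per residue along the helix axis
TWIST = math.radians(32.7)  # per residue
C3_RADIUS = 9.4  # Å, C3' distance from the helix axis
C1_RADIUS = 5.2
LINKER_STEP = 6.0  # Å between consecutive C3' atoms off-helix

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
TARGET_NAME = "target"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic benchmark instance."""

    n_homologs: int = 5
    core_len: int = 20
    n_models_per_homolog: int = 100
    n_clusters: int = 3
    within_sigma: float = 1.0  # Å RMS per-atom displacement inside a cluster
    between_shift: float = 12.0  # Å hinge displacement separating clusters
    helix_fraction: float = 0.6
    insert_lens: tuple[int, ...] | None = None  # per homolog; default 2+h
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_homologs < 2:
            raise ParameterError("need at least 2 homologs (target included)")
        if self.core_len < 8:
            raise ParameterError("core_len must be >= 8")
        if self.n_models_per_homolog < 1 or self.n_clusters < 1:
            raise ParameterError("model and cluster counts must be positive")
        if self.within_sigma < 0 or self.between_shift < 0:
            raise ParameterError("noise parameters must be non-negative")
        if not 0.0 <= self.helix_fraction <= 1.0:
            raise ParameterError("helix_fraction must be in [0, 1]")
        if self.insert_lens is not None and len(self.insert_lens) != self.n_homologs:
            raise ParameterError("insert_lens must have one entry per homolog")
        if self.n_clusters > 1 and self.between_shift <= 4 * self.within_sigma:
            warnings.warn(
                "between_shift <= 4*within_sigma: planted clusters may not be "
                "separable", stacklevel=2,
            )

    def resolved_insert_lens(self) -> tuple[int, ...]:
        if self.insert_lens is not None:
            return self.insert_lens
        return tuple(2 + h for h in range(self.n_homologs))


class GroundTruth(NamedTuple):
    """Planted labels and the unperturbed target reference."""

    labels: dict[str, int]  # model_id → planted cluster index
    reference_model: StructureModel
    reference_ss: str  # dot-bracket over the full target chain


class Backbone(NamedTuple):
    model: StructureModel
    ss: str  # dot-bracket over the core


class SyntheticDataset(NamedTuple):
    alignment: Alignment
    model_set: ModelSet
    truth: GroundTruth
    core_columns: tuple[int, ...]


def _frame_residue(
    letter: str, pos: np.ndarray, d: np.ndarray, n: np.ndarray
) -> Residue:
    """Off-helix residue: atoms laid out in the (d, n) local frame."""
    b = np.cross(d, n)
    atoms = {
        "P": pos + 1.5 * n + 0.9 * d,
        "C3'": pos.copy(),
        "C1'": pos + 4.2 * n,
        "N1": pos + 6.0 * n,
        "C2": pos + 7.0 * n + 1.2 * d,
        "N3": pos + 7.0 * n - 1.2 * d,
        "C4": pos + 8.0 * n + 0.0 * b,
    }
    return Residue(letter, atoms)


def _helix_residue(letter: str, theta: float, z: float) -> Residue:
    """Helical residue: base atoms horizontal, pointing at the axis."""
    u = np.array([math.cos(theta), math.sin(theta), 0.0])
    t = np.array([-math.sin(theta), math.cos(theta), 0.0])
    zv = np.array([0.0, 0.0, z])
    atoms = {
        "P": C3_RADIUS * u + 1.0 * t + zv + np.array([0.0, 0.0, 1.6]),
        "C3'": C3_RADIUS * u + zv,
        "C1'": C1_RADIUS * u + zv,
        "N1": 1.7 * u + zv,
        "C2": 3.3 * u + 1.2 * t + zv,
        "N3": 3.3 * u - 1.2 * t + zv,
        "C4": 4.6 * u + zv,
    }
    return Residue(letter, atoms)


def _arc_points(a: np.ndarray, b: np.ndarray, n_pts: int) -> list[np.ndarray]:
    """``n_pts`` points between a and b with near-uniform ~6 Å chords.

    Straight-line interpolation when the straight spacing already reaches
    the linker step; otherwise the points sit on a circular arc bulging in
    +z, with the subtended angle solved so every chord equals the step.
    """
    chord = float(np.linalg.norm(b - a))
    e1 = (b - a) / chord
    up = np.array([0.0, 0.0, 1.0])
    e2 = up - (up @ e1) * e1
    if np.linalg.norm(e2) < 1e-6:
        e2 = np.array([1.0, 0.0, 0.0]) - (e1[0]) * e1
    e2 /= np.linalg.norm(e2)

    if chord / (n_pts + 1) >= LINKER_STEP:
        return [a + (b - a) * (k / (n_pts + 1)) for k in range(1, n_pts + 1)]

    seg = n_pts + 1

    def gap(alpha: float) -> float:
        return chord * math.sin(alpha / (2 * seg)) / math.sin(alpha / 2) - LINKER_STEP

    hi = 2 * math.pi - 0.1
    alpha = hi if gap(hi) < 0 else brentq(gap, 1e-9, hi)
    radius = chord / (2 * math.sin(alpha / 2))
    mid = (a + b) / 2
    center = mid - radius * math.cos(alpha / 2) * e2
    # A sits at angle 90°+α/2 and B at 90°−α/2 on this circle, so a uniform
    # angular sweep passes over the +e2 bulge with equal chords throughout.
    phi_a = math.pi / 2 + alpha / 2
    pts = []
    for k in range(1, n_pts + 1):
        phi = phi_a - k * alpha / seg
        pts.append(center + radius * (math.cos(phi) * e1 + math.sin(phi) * e2))
    return pts


def make_backbone(
    core_len: int, helix_fraction: float = 0.6, rng: np.random.Generator | None = None
) -> Backbone:
    """Idealized core backbone with a planted secondary structure.

    The paired fraction forms an antiparallel hairpin stem on a common
    axis; unpaired residues bridge the two strands as a smooth linker (or
    the whole chain is extended when the fraction is too small for a
    stem). Consecutive C3'-C3' distances stay near 6 Å except at a
    loop-less stem junction.
    """
    if core_len < 8:
        raise ParameterError("core_len must be >= 8")
    rng = rng or np.random.default_rng(0)
    n_pairs = int(core_len * helix_fraction) // 2
    if n_pairs < 2:
        n_pairs = 0

    # sequence: random, complementary across planted pairs
    letters = [str(x) for x in rng.choice(list("ACGU"), size=core_len)]
    for i in range(n_pairs):
        letters[core_len - 1 - i] = _COMPLEMENT[letters[i]]

    residues: list[Residue | None] = [None] * core_len
    if n_pairs == 0:
        d = np.array([1.0, 0.0, 0.0])
        n = np.array([0.0, 0.0, 1.0])
        for i in range(core_len):
            pos = np.array([LINKER_STEP * i, 0.0, 0.0])
            residues[i] = _frame_residue(letters[i], pos, d, n)
        ss = "." * core_len
        model = StructureModel("backbone", TARGET_NAME, 1, tuple(residues))
        return Backbone(model, ss)

    for i in range(n_pairs):
        theta = i * TWIST
        z = i * RISE
        residues[i] = _helix_residue(letters[i], theta, z)
        residues[core_len - 1 - i] = _helix_residue(
            letters[core_len - 1 - i], theta + math.pi, z
        )
    n_loop = core_len - 2 * n_pairs
    if n_loop:
        a = residues[n_pairs - 1].atoms["C3'"]
        b = residues[core_len - n_pairs].atoms["C3'"]
        pts = _arc_points(a, b, n_loop)
        path = [a] + pts + [b]
        for k in range(n_loop):
            pos = path[k + 1]
            d = path[k + 2] - path[k]
            d = d / np.linalg.norm(d)
            up = np.array([0.0, 0.0, 1.0])
            n = up - (up @ d) * d
            if np.linalg.norm(n) < 1e-6:
                n = np.array([1.0, 0.0, 0.0])
            n /= np.linalg.norm(n)
            residues[n_pairs + k] = _frame_residue(letters[n_pairs + k], pos, d, n)
    ss = "(" * n_pairs + "." * n_loop + ")" * n_pairs
    model = StructureModel("backbone", TARGET_NAME, 1, tuple(residues))
    return Backbone(model, ss)


def _homolog_names(n_homologs: int) -> list[str]:
    return [TARGET_NAME] + [f"hom{h}" for h in range(1, n_homologs)]


def _insert_positions(spec: SyntheticSpec) -> list[int]:
    # one insertion site per homolog, spread along the core, never at the ends
    return [
        max(1, min(spec.core_len - 1, (h + 1) * spec.core_len // (spec.n_homologs + 1)))
        for h in range(spec.n_homologs)
    ]


def _cluster_transform(
    k: int, between_shift: float, pivot: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rigid motion of the mobile half for planted cluster k (0 = identity)."""
    if k == 0:
        return np.eye(3), np.zeros(3)
    axis = np.array([math.sin(2.1 * k), math.cos(2.1 * k), 0.7])
    axis /= np.linalg.norm(axis)
    rot = Rotation.from_rotvec(math.radians(25.0 * k) * axis).as_matrix()
    direction = np.array([math.cos(2.4 * k), math.sin(2.4 * k), 0.35])
    direction /= np.linalg.norm(direction)
    shift = k * between_shift * direction
    # p -> rot @ (p - pivot) + pivot + shift
    return rot, pivot - rot @ pivot + shift


def _transform_residue(res: Residue, rot: np.ndarray, trans: np.ndarray) -> Residue:
    return Residue(res.res_name, {a: rot @ xyz + trans for a, xyz in res.atoms.items()})


def _jitter_residue(res: Residue, rng: np.random.Generator, sigma: float) -> Residue:
    # sigma is the RMS 3D displacement per atom, so each coordinate gets
    # sigma/sqrt(3); two same-cluster decoys then sit ~ sigma*sqrt(2) apart
    # in core RMSD before the superposition correction.
    if sigma == 0:
        return res
    scale = sigma / math.sqrt(3.0)
    return Residue(
        res.res_name,
        {a: xyz + rng.normal(0.0, scale, size=3) for a, xyz in res.atoms.items()},
    )


def make_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the alignment, decoy model set and ground truth in memory."""
    rng = np.random.default_rng(spec.seed)
    bb_model, core_ss = make_backbone(spec.core_len, spec.helix_fraction, rng)
    names = _homolog_names(spec.n_homologs)
    ins_lens = spec.resolved_insert_lens()
    ins_pos = _insert_positions(spec)

    # sequences: target's core sequence, mutated per homolog
    target_core = [res.res_name for res in bb_model.residues]
    core_seqs: dict[str, list[str]] = {TARGET_NAME: target_core}
    for name in names[1:]:
        seq = []
        for ch in target_core:
            if rng.random() < 0.25:
                seq.append(str(rng.choice([x for x in "ACGU" if x != ch])))
            else:
                seq.append(ch)
        core_seqs[name] = seq
    insert_seqs = {
        name: [str(x) for x in rng.choice(list("ACGU"), size=ins_lens[h])]
        for h, name in enumerate(names)
    }

    # gapped alignment rows: core columns with per-homolog insert blocks
    rows = {name: [] for name in names}
    core_columns: list[int] = []
    col = 0
    for c in range(spec.core_len + 1):
        for h, name in enumerate(names):
            if ins_pos[h] == c and ins_lens[h] > 0:
                for letter in insert_seqs[name]:
                    for other in names:
                        rows[other].append(letter if other == name else "-")
                    col += 1
        if c == spec.core_len:
            break
        for name in names:
            rows[name].append(core_seqs[name][c])
        core_columns.append(col)
        col += 1
    alignment = Alignment(tuple((name, "".join(rows[name])) for name in names))

    # idealized full chains per homolog, and the hinge index in chain space
    hinge_core = spec.core_len // 2
    pivot = bb_model.residues[hinge_core - 1].atoms["C3'"].copy()
    chains: dict[str, list[Residue]] = {}
    hinges: dict[str, int] = {}
    for h, name in enumerate(names):
        chain: list[Residue] = []
        attach_axis = math.radians(137.5) * h + 0.7
        direction = np.array(
            [math.cos(attach_axis), math.sin(attach_axis), -0.6]
        )
        direction /= np.linalg.norm(direction)
        up = np.array([0.0, 0.0, 1.0])
        n_vec = up - (up @ direction) * direction
        n_vec /= np.linalg.norm(n_vec)
        for c in range(spec.core_len + 1):
            if ins_pos[h] == c and ins_lens[h] > 0:
                anchor = bb_model.residues[max(c - 1, 0)].atoms["C3'"]
                for j, letter in enumerate(insert_seqs[name]):
                    pos = anchor + (j + 1) * LINKER_STEP * direction
                    chain.append(_frame_residue(letter, pos, direction, n_vec))
            if c == spec.core_len:
                break
            core_res = bb_model.residues[c]
            chain.append(Residue(core_seqs[name][c], dict(core_res.atoms)))
        chains[name] = chain
        hinges[name] = hinge_core + (ins_lens[h] if ins_pos[h] <= hinge_core else 0)

    # cluster weights: a dominant conformation plus progressively rarer ones
    weights = np.array([2.0 ** (spec.n_clusters - k) for k in range(spec.n_clusters)])
    weights /= weights.sum()
    transforms = [
        _cluster_transform(k, spec.between_shift, pivot)
        for k in range(spec.n_clusters)
    ]

    models: list[StructureModel] = []
    labels: dict[str, int] = {}
    for name in names:
        chain = chains[name]
        hinge = hinges[name]
        assigned = rng.choice(spec.n_clusters, size=spec.n_models_per_homolog, p=weights)
        for rank, k in enumerate(assigned, start=1):
            rot, trans = transforms[int(k)]
            residues = []
            for idx, res in enumerate(chain):
                moved = _transform_residue(res, rot, trans) if idx >= hinge else res
                residues.append(_jitter_residue(moved, rng, spec.within_sigma))
            mid = make_model_id(name, rank)
            models.append(StructureModel(mid, name, rank, tuple(residues)))
            labels[mid] = int(k)
    model_set = ModelSet(models=tuple(models), target_name=TARGET_NAME)

    # reference: unperturbed target chain; secondary structure with the
    # target's insertion spliced in as unpaired positions
    reference = StructureModel(
        "reference", TARGET_NAME, 1, tuple(chains[TARGET_NAME])
    )
    t_pos, t_len = ins_pos[0], ins_lens[0]
    reference_ss = core_ss[:t_pos] + "." * t_len + core_ss[t_pos:]
    truth = GroundTruth(
        labels=labels, reference_model=reference, reference_ss=reference_ss
    )
    return SyntheticDataset(alignment, model_set, truth, tuple(core_columns))


class FixturePaths(NamedTuple):
    alignment: Path
    models_dir: Path
    mapping: Path
    reference: Path
    reference_ss: Path
    ground_truth: Path


def make_fixture(spec: SyntheticSpec, out_dir: str | Path) -> tuple[FixturePaths, GroundTruth]:
    """Write a complete input fixture to disk (deterministic for a seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = make_dataset(spec)

    aln_path = out / "alignment.fasta"
    aln_path.write_text(
        "".join(f">{name}\n{seq}\n" for name, seq in ds.alignment.records)
    )

    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    for m in ds.model_set.models:
        write_pdb(m, models_dir / f"{m.homolog}_{m.rank:03d}.pdb")

    mapping = out / "mapping.tsv"
    mapping.write_text(
        "".join(f"{name}\t{name}_*.pdb\n" for name in _homolog_names(spec.n_homologs))
    )

    ref_path = out / "reference.pdb"
    write_pdb(ds.truth.reference_model, ref_path)
    ss_path = out / "reference_ss.txt"
    ss_path.write_text(ds.truth.reference_ss + "\n")

    gt_path = out / "ground_truth.json"
    gt_path.write_text(
        json.dumps(
            {
                "target": TARGET_NAME,
                "labels": ds.truth.labels,
                "reference_ss": ds.truth.reference_ss,
                "core_columns": list(ds.core_columns),
            },
            indent=0,
            sort_keys=True,
        )
        + "\n"
    )
    return (
        FixturePaths(aln_path, models_dir, mapping, ref_path, ss_path, gt_path),
        ds.truth,
    )
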