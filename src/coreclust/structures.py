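"""PDB decoy input: residue-ordered coordinates and ranked model sets.

Decoy generators renumber residues inconsistently, so residue identity
here is positional (chain order as read), matching the positional residue
indices produced by :mod:`coreclust.msa`. Every residue must carry a C3'
atom — the single backbone atom used for cross-homolog comparison — or the
model is rejected at load time.
"""

from __future__ import annotations

import glob as globmod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio.PDB import PDBParser

from .errors import StructureError

C3_PRIME = "C3'"


def _normalize_atom_name(name: str) -> str:
    """Map legacy PDB primes (C3*) onto the modern convention (C3')."""
    return name.strip().replace("*", "'")


def is_hydrogen(atom_name: str) -> bool:
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped.startswith(("H", "D"))


@dataclass(frozen=True)
class Residue:
    """One nucleotide: residue name plus atom-name → coordinate map (Å)."""

    res_name: str
    atoms: dict[str, np.ndarray]

    def coord(self, atom_name: str) -> np.ndarray:
        try:
            return self.atoms[atom_name]
        except KeyError:
            raise StructureError(
                f"residue {self.res_name} has no atom '{atom_name}'"
            ) from None


@dataclass(frozen=True)
class StructureModel:
    """A single decoy (or reference) structure.

    ``homolog`` names the alignment sequence the model was folded for and
    ``rank`` its position in the energy ordering of that homolog's decoy
    set (1 = lowest energy).
    """

    model_id: str
    homolog: str
    rank: int
    residues: tuple[Residue, ...]
    source: Path | None = None

    def __post_init__(self) -> None:
        for i, res in enumerate(self.residues):
            if C3_PRIME not in res.atoms:
                raise StructureError(
                    f"model {self.model_id}: residue {i + 1} ({res.res_name}) "
                    f"lacks a {C3_PRIME} atom"
                )
            for name, xyz in res.atoms.items():
                if not np.all(np.isfinite(xyz)):
                    raise StructureError(
                        f"model {self.model_id}: non-finite coordinate for "
                        f"atom {name} of residue {i + 1}"
                    )

    def __len__(self) -> int:
        return len(self.residues)


def read_pdb(
    path: str | Path,
    model_id: str | None = None,
    homolog: str = "",
    rank: int = 1,
) -> StructureModel:
    """Parse one structure from a PDB file.

    Chains are concatenated in file order; only the first MODEL of a
    multi-model file is read; HETATM ligands and waters are skipped;
    altloc atoms other than blank/'A' are ignored; legacy ``C3*`` names
    are normalized to ``C3'``.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"PDB file not found: {path}")
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises assorted types on malformed files
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise StructureError(f"no ATOM records in {path}")
    first = models[0]

    residues: list[Residue] = []
    for chain in first:
        for res in chain:
            hetfield = res.id[0]
            if hetfield != " ":
                continue  # HETATM ligand / water
            atoms: dict[str, np.ndarray] = {}
            for atom in res.get_unpacked_list():
                altloc = atom.get_altloc()
                if altloc not in (" ", "A"):
                    continue
                name = _normalize_atom_name(atom.get_name())
                if name not in atoms:
                    atoms[name] = np.asarray(atom.get_coord(), dtype=float)
            if atoms:
                residues.append(Residue(res.resname.strip(), atoms))
    if not residues:
        raise StructureError(f"no ATOM records in {path}")
    return StructureModel(
        model_id=model_id or path.stem,
        homolog=homolog,
        rank=rank,
        residues=tuple(residues),
        source=path,
    )


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a model as plain ATOM records (one chain, 3-decimal Å)."""
    lines = []
    serial = 1
    for i, res in enumerate(model.residues):
        for name, xyz in res.atoms.items():
            pdb_name = name.replace("'", "'")
            # columns 13-16: names <4 chars start in column 14
            field_name = f" {pdb_name:<3s}" if len(pdb_name) < 4 else pdb_name[:4]
            element = "H" if is_hydrogen(name) else name.strip("0123456789'")[:1]
            lines.append(
                f"ATOM  {serial:5d} {field_name} {res.res_name:>3s} A{i + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class ModelSet:
    """Ranked decoy models grouped by homolog, plus the target's name."""

    models: tuple[StructureModel, ...]
    target_name: str

    def __post_init__(self) -> None:
        by_hom: dict[str, list[int]] = {}
        for m in self.models:
            by_hom.setdefault(m.homolog, []).append(m.rank)
        if self.target_name not in by_hom:
            raise StructureError(
                f"target '{self.target_name}' has no models in the set"
            )
        for hom, ranks in by_hom.items():
            if sorted(ranks) != list(range(1, len(ranks) + 1)):
                raise StructureError(
                    f"ranks for homolog '{hom}' are not contiguous from 1"
                )
        ids = [m.model_id for m in self.models]
        if len(set(ids)) != len(ids):
            raise StructureError("duplicate model_id in model set")

    @property
    def homologs(self) -> tuple[str, ...]:
        seen: list[str] = []
        for m in self.models:
            if m.homolog not in seen:
                seen.append(m.homolog)
        return tuple(seen)

    def homolog_by_id(self) -> dict[str, str]:
        return {m.model_id: m.homolog for m in self.models}

    def rank_by_id(self) -> dict[str, int]:
        return {m.model_id: m.rank for m in self.models}

    def by_id(self, model_id: str) -> StructureModel:
        for m in self.models:
            if m.model_id == model_id:
                return m
        raise KeyError(model_id)

    def of_homolog(self, homolog: str) -> tuple[StructureModel, ...]:
        return tuple(m for m in self.models if m.homolog == homolog)

    def __len__(self) -> int:
        return len(self.models)


def make_model_id(homolog: str, rank: int) -> str:
    """Canonical model identifier; zero-padded so id order follows rank."""
    return f"{homolog}#{rank:03d}"


def rank_from_id(model_id: str) -> int:
    """Best-effort rank recovery from a canonical model id (else 0)."""
    _, _, tail = model_id.rpartition("#")
    try:
        return int(tail)
    except ValueError:
        return 0


def _parse_mapping(mapping_path: Path) -> dict[str, list[tuple[str, int | None]]]:
    entries: dict[str, list[tuple[str, int | None]]] = {}
    two_col: set[str] = set()
    for lineno, raw in enumerate(mapping_path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 2:
            name, pattern = fields
            if name in entries:
                raise StructureError(
                    f"{mapping_path}:{lineno}: duplicate sequence name '{name}'"
                )
            entries[name] = [(pattern, None)]
            two_col.add(name)
        elif len(fields) == 3:
            name, filename, rank_s = fields
            if name in two_col:
                raise StructureError(
                    f"{mapping_path}:{lineno}: '{name}' mixes glob and "
                    "explicit-rank mapping lines"
                )
            try:
                rank = int(rank_s)
            except ValueError:
                raise StructureError(
                    f"{mapping_path}:{lineno}: rank '{rank_s}' is not an integer"
                ) from None
            entries.setdefault(name, []).append((filename, rank))
        else:
            raise StructureError(
                f"{mapping_path}:{lineno}: expected 2 or 3 tab-separated fields"
            )
    if not entries:
        raise StructureError(f"mapping file {mapping_path} is empty")
    return entries


def load_model_set(
    models_dir: str | Path,
    mapping: str | Path,
    per_homolog_limit: int = 100,
    target_name: str | None = None,
) -> ModelSet:
    """Load ranked decoy sets for every homolog in a mapping file.

    The mapping file is TSV: either ``name<TAB>glob`` (files matching the
    glob, sorted lexicographically, define the energy rank order) or
    explicit ``name<TAB>filename<TAB>rank`` lines. Only the first
    ``per_homolog_limit`` models per homolog are retained; the target
    defaults to the first homolog of the mapping.
    """
    if per_homolog_limit < 1:
        raise StructureError("per_homolog_limit must be >= 1")
    models_dir = Path(models_dir)
    entries = _parse_mapping(Path(mapping))

    models: list[StructureModel] = []
    for homolog, specs in entries.items():
        if specs[0][1] is None:  # glob form
            pattern = specs[0][0]
            files = sorted(globmod.glob(str(models_dir / pattern)))
        else:  # explicit rank form
            ordered = sorted(specs, key=lambda fr: fr[1])
            files = [str(models_dir / fname) for fname, _ in ordered]
            missing = [f for f in files if not Path(f).exists()]
            if missing:
                raise StructureError(
                    f"homolog '{homolog}': mapped file not found: {missing[0]}"
                )
        if not files:
            raise StructureError(
                f"homolog '{homolog}': no model files match in {models_dir}"
            )
        for rank, fname in enumerate(files[:per_homolog_limit], start=1):
            models.append(
                read_pdb(
                    fname,
                    model_id=make_model_id(homolog, rank),
                    homolog=homolog,
                    rank=rank,
                )
            )
    target = target_name if target_name is not None else next(iter(entries))
    return ModelSet(models=tuple(models), target_name=target)
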