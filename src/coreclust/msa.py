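"""Multiple sequence alignments and the conserved core.

Homologous RNAs from one family are assumed to share a structurally
conserved core: the alignment columns at which every selected sequence has
a residue. This module parses alignments (Stockholm, aligned FASTA,
Clustal), removes near-identical sequences, and maps core columns to
per-sequence residue indices so that structural coordinates of different
homologs become directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO

from .errors import AlignmentFormatError, EmptyCoreError, ParameterError

GAP_CHARS = frozenset("-.")
#: Unambiguous RNA letters; anything else (N, R, Y, ...) is carried through
#: the alignment but never counts as a match in identity computations.
RNA_LETTERS = frozenset("ACGU")

ALIGNMENT_FORMATS = ("stockholm", "fasta", "clustal")


def normalize_seq(seq: str) -> str:
    """Uppercase, DNA→RNA (T→U) and '.'→'-' gap normalization."""
    return seq.upper().replace("T", "U").replace(".", "-")


@dataclass(frozen=True)
class Alignment:
    """An ordered, rectangular multiple sequence alignment.

    ``records`` is a tuple of ``(name, gapped_seq)`` pairs; all gapped
    sequences have equal length and names are unique. Sequences are stored
    normalized (uppercase RNA, '-' gaps).
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentFormatError("alignment has no records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            bad = next(
                name
                for name, seq in self.records
                if len(seq) != len(self.records[0][1])
            )
            raise AlignmentFormatError(
                f"ragged alignment: record '{bad}' has a different length"
            )
        names = [name for name, _ in self.records]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise AlignmentFormatError(f"duplicate record name '{dup}'")

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.records[0][1])

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.records)

    def seq(self, name: str) -> str:
        for n, s in self.records:
            if n == name:
                return s
        raise KeyError(name)

    def ungapped(self, name: str) -> str:
        return "".join(c for c in self.seq(name) if c not in GAP_CHARS)

    def __len__(self) -> int:
        return len(self.records)


def _alignment_from_pairs(pairs: Iterable[tuple[str, str]]) -> Alignment:
    return Alignment(tuple((name, normalize_seq(seq)) for name, seq in pairs))


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read and normalize an alignment file.

    Parameters
    ----------
    path:
        Alignment file.
    format:
        One of ``stockholm``, ``fasta`` (aligned FASTA) or ``clustal``.
    """
    path = Path(path)
    if format not in ALIGNMENT_FORMATS:
        raise ParameterError(
            f"unknown alignment format '{format}'; expected one of "
            f"{', '.join(ALIGNMENT_FORMATS)}"
        )
    if not path.exists():
        raise AlignmentFormatError(f"alignment file not found: {path}")
    if format == "fasta":
        # SeqIO first so ragged input can be blamed on a named record.
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentFormatError(f"no sequences found in {path}")
        width = len(records[0].seq)
        for rec in records:
            if len(rec.seq) != width:
                raise AlignmentFormatError(
                    f"ragged alignment in {path}: record '{rec.id}' has "
                    f"length {len(rec.seq)}, expected {width}"
                )
        return _alignment_from_pairs((rec.id, str(rec.seq)) for rec in records)
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise AlignmentFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    return _alignment_from_pairs((rec.id, str(rec.seq)) for rec in msa)


def pairwise_identity(a: str, b: str) -> float:
    """Fractional identity between two gapped rows of equal length.

    The denominator counts columns where at least one of the pair is
    non-gap (gap-gap columns are ignored); a match requires the same
    unambiguous RNA letter in both. Returns 0.0 when the denominator is 0.
    """
    if len(a) != len(b):
        raise ParameterError("identity requires equally long gapped rows")
    matches = 0
    aligned = 0
    for x, y in zip(a, b):
        xg = x in GAP_CHARS
        yg = y in GAP_CHARS
        if xg and yg:
            continue
        aligned += 1
        if x == y and x in RNA_LETTERS:
            matches += 1
    return matches / aligned if aligned else 0.0


def reduce_redundancy(aln: Alignment, identity_threshold: float = 0.9) -> Alignment:
    """Greedy removal of near-identical sequences.

    Records are scanned in order; a record is dropped when its pairwise
    identity with any already-kept record reaches ``identity_threshold``.
    The greedy scan is deterministic, so the first of a redundant group is
    the one retained.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ParameterError(
            f"identity_threshold must be in (0, 1], got {identity_threshold}"
        )
    kept: list[tuple[str, str]] = []
    for name, seq in aln.records:
        if all(pairwise_identity(seq, k) < identity_threshold for _, k in kept):
            kept.append((name, seq))
    return Alignment(tuple(kept))


@dataclass(frozen=True)
class CoreMap:
    """Conserved core columns and their per-sequence residue indices.

    ``columns`` are 0-based alignment column indices, strictly increasing.
    ``per_seq[name][k]`` is the 0-based index, in the ungapped sequence
    ``name``, of the residue sitting in alignment column ``columns[k]``.
    """

    columns: tuple[int, ...]
    per_seq: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.columns, self.columns[1:])):
            raise ParameterError("core columns must be strictly increasing")
        for name, idxs in self.per_seq.items():
            if len(idxs) != len(self.columns):
                raise ParameterError(
                    f"residue index list for '{name}' does not match core size"
                )
            if any(b <= a for a, b in zip(idxs, idxs[1:])):
                raise ParameterError(
                    f"residue indices for '{name}' must be strictly increasing"
                )

    @property
    def size(self) -> int:
        return len(self.columns)

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as tab-separated text (lossless round-trip)."""
        lines = ["#columns\t" + "\t".join(str(c) for c in self.columns)]
        for name, idxs in self.per_seq.items():
            lines.append(name + "\t" + "\t".join(str(i) for i in idxs))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CoreMap":
        lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
        if not lines or not lines[0].startswith("#columns"):
            raise ParameterError(f"{path} is not a core-map TSV")
        columns = tuple(int(x) for x in lines[0].split("\t")[1:])
        per_seq: dict[str, tuple[int, ...]] = {}
        for ln in lines[1:]:
            fields = ln.split("\t")
            per_seq[fields[0]] = tuple(int(x) for x in fields[1:])
        return cls(columns=columns, per_seq=per_seq)


def conserved_core(
    aln: Alignment,
    selected: Sequence[str],
    min_ungapped_fraction: float = 1.0,
) -> CoreMap:
    """Determine the columns common to all selected sequences.

    With the default ``min_ungapped_fraction`` of 1.0 a column belongs to
    the core exactly when every selected sequence has a residue there.
    Lower fractions admit columns gapped in a minority of the selected
    sequences, but every sequence for which a residue map is produced must
    still be ungapped at every retained column (an informative error is
    raised otherwise) — the relaxed fraction is useful for diagnosing which
    sequences break the core, then re-selecting.
    """
    if not 0.0 < min_ungapped_fraction <= 1.0:
        raise ParameterError(
            f"min_ungapped_fraction must be in (0, 1], got {min_ungapped_fraction}"
        )
    selected = list(selected)
    if len(selected) < 2:
        raise ParameterError("conserved core needs at least two selected sequences")
    missing = [s for s in selected if s not in aln.names]
    if missing:
        raise ParameterError(f"selected sequences not in alignment: {missing}")

    rows = {name: aln.seq(name) for name in selected}
    need = min_ungapped_fraction * len(selected)
    columns = []
    for col in range(aln.length):
        ungapped = sum(rows[name][col] not in GAP_CHARS for name in selected)
        if ungapped >= need - 1e-9:
            columns.append(col)
    if not columns:
        raise EmptyCoreError(
            "no alignment column is ungapped in all selected sequences; "
            "revise the alignment or the selection of homologs"
        )

    per_seq: dict[str, tuple[int, ...]] = {}
    for name in selected:
        row = rows[name]
        gapped_at = [c for c in columns if row[c] in GAP_CHARS]
        if gapped_at:
            raise EmptyCoreError(
                f"sequence '{name}' is gapped at retained core column(s) "
                f"{gapped_at[:5]}; drop it from the selection or keep "
                "min_ungapped_fraction at 1.0"
            )
        # residue index = number of residues strictly before the column
        counts = []
        running = 0
        it = iter(columns)
        nxt = next(it)
        for col, ch in enumerate(row):
            if col == nxt:
                counts.append(running)
                try:
                    nxt = next(it)
                except StopIteration:
                    nxt = -1
            if ch not in GAP_CHARS:
                running += 1
        per_seq[name] = tuple(counts)
    return CoreMap(columns=tuple(columns), per_seq=per_seq)
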