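"""Export a core-RMSD matrix as a CLANS cluster-map file.

CLANS lays out a graph from pairwise attraction values; feeding it
structural similarities instead of sequence similarities turns the
all-vs-all core-RMSD matrix into an interactive cluster map. Model pairs
closer than a distance threshold are connected with attraction
``1 - d/threshold`` (any strictly decreasing map yields the same graph
topology); each homolog gets its own color group, the target is lime, and
an optional experimental reference structure is appended as an extra node
with its own distances. Documented presets from published cluster maps:
6 Å (a ribozyme ensemble) and 9 Å (a riboswitch ensemble).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ParameterError
from .geometry import CoreTrace, DistanceMatrix, kabsch_rmsd

TARGET_COLOR = (0, 255, 0)  # lime
REFERENCE_COLOR = (255, 0, 0)
_PALETTE = (
    (31, 119, 180),
    (255, 127, 14),
    (148, 103, 189),
    (140, 86, 75),
    (227, 119, 194),
    (127, 127, 127),
    (188, 189, 34),
    (23, 190, 207),
)

REFERENCE_GROUP = "reference"


@dataclass(frozen=True)
class ClansDocument:
    """In-memory form of a CLANS file."""

    ids: tuple[str, ...]
    seq_len: int
    groups: tuple[tuple[str, tuple[int, int, int], tuple[int, ...]], ...]
    connections: tuple[tuple[int, int, float], ...]  # (i, j, attraction), i < j

    @property
    def n(self) -> int:
        return len(self.ids)


def to_clans(
    matrix: DistanceMatrix,
    groups: Mapping[str, str],
    threshold: float,
    target: str | None = None,
    reference: CoreTrace | None = None,
    traces: Sequence[CoreTrace] | None = None,
) -> ClansDocument:
    """Build a CLANS document from a distance matrix.

    ``groups`` maps every model_id to its homolog name; ``target`` (if
    given) selects the homolog colored lime. With ``reference`` (and the
    per-model ``traces``, ordered like the matrix ids) the reference
    structure is appended as an extra node in its own group.
    """
    if threshold <= 0:
        raise ParameterError(f"threshold must be > 0, got {threshold}")
    missing = [mid for mid in matrix.ids if mid not in groups]
    if missing:
        raise ParameterError(f"models missing from groups mapping: {missing[:5]}")

    ids = list(matrix.ids)
    values = matrix.values
    if reference is not None:
        if traces is None or len(traces) != len(matrix):
            raise ParameterError(
                "reference export needs one CoreTrace per matrix id"
            )
        ref_row = np.array(
            [kabsch_rmsd(reference.points, t.points) for t in traces]
        )
        n = len(ids)
        ext = np.zeros((n + 1, n + 1))
        ext[:n, :n] = values
        ext[n, :n] = ref_row
        ext[:n, n] = ref_row
        values = ext
        ids.append(reference.model_id)

    homolog_order: list[str] = []
    for mid in matrix.ids:
        hom = groups[mid]
        if hom not in homolog_order:
            homolog_order.append(hom)
    group_list = []
    palette_idx = 0
    for hom in homolog_order:
        if target is not None and hom == target:
            color = TARGET_COLOR
        else:
            color = _PALETTE[palette_idx % len(_PALETTE)]
            palette_idx += 1
        members = tuple(
            i for i, mid in enumerate(matrix.ids) if groups[mid] == hom
        )
        group_list.append((hom, color, members))
    if reference is not None:
        group_list.append((REFERENCE_GROUP, REFERENCE_COLOR, (len(ids) - 1,)))

    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    below = values[iu, ju] < threshold
    connections = tuple(
        (int(i), int(j), float(1.0 - values[i, j] / threshold))
        for i, j in zip(iu[below], ju[below])
    )
    seq_len = len(traces[0].points) if traces else 10
    return ClansDocument(
        ids=tuple(ids),
        seq_len=seq_len,
        groups=tuple(group_list),
        connections=connections,
    )


def write_clans(doc: ClansDocument, path: str | Path) -> None:
    """Serialize in the CLANS file dialect."""
    lines = [f"sequences={doc.n}", "<seq>"]
    for mid in doc.ids:
        lines.append(f">{mid}")
        lines.append("N" * doc.seq_len)
    lines.append("</seq>")
    lines.append("<seqgroups>")
    for name, color, members in doc.groups:
        lines.append(f"name={name}")
        lines.append(f"color={color[0]};{color[1]};{color[2]};255")
        lines.append("numbers=" + ";".join(str(m) for m in members))
    lines.append("</seqgroups>")
    lines.append("<hsp>")
    for i, j, att in doc.connections:
        lines.append(f"{i} {j}:{att:.6f}")
    lines.append("</hsp>")
    Path(path).write_text("\n".join(lines) + "\n")


def read_clans(path: str | Path) -> ClansDocument:
    """Parse a file written by :func:`write_clans` (round-trip reader)."""
    text = Path(path).read_text().splitlines()
    it = iter(text)
    first = next(it)
    if not first.startswith("sequences="):
        raise ParameterError(f"{path} is not a CLANS file")
    n = int(first.split("=")[1])
    ids: list[str] = []
    seq_len = 10
    groups: list[tuple[str, tuple[int, int, int], tuple[int, ...]]] = []
    connections: list[tuple[int, int, float]] = []
    section = None
    pending_name = None
    pending_color = None
    for line in it:
        line = line.strip()
        if not line:
            continue
        if line in ("<seq>", "<seqgroups>", "<hsp>"):
            section = line
            continue
        if line in ("</seq>", "</seqgroups>", "</hsp>"):
            section = None
            continue
        if section == "<seq>":
            if line.startswith(">"):
                ids.append(line[1:])
            else:
                seq_len = len(line)
        elif section == "<seqgroups>":
            if line.startswith("name="):
                pending_name = line[5:]
            elif line.startswith("color="):
                r, g, b = (int(x) for x in line[6:].split(";")[:3])
                pending_color = (r, g, b)
            elif line.startswith("numbers="):
                members = tuple(
                    int(x) for x in line[8:].split(";") if x != ""
                )
                groups.append((pending_name, pending_color, members))
        elif section == "<hsp>":
            left, att = line.rsplit(":", 1)
            i, j = (int(x) for x in left.split())
            connections.append((i, j, float(att)))
    if len(ids) != n:
        raise ParameterError(
            f"{path}: header promises {n} sequences, found {len(ids)}"
        )
    return ClansDocument(
        ids=tuple(ids),
        seq_len=seq_len,
        groups=tuple(groups),
        connections=tuple(connections),
    )
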