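from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coreclust.errors import AlignmentFormatError, EmptyCoreError, ParameterError
from coreclust.msa import (
    GAP_CHARS,
    Alignment,
    CoreMap,
    conserved_core,
    pairwise_identity,
    read_alignment,
    reduce_redundancy,
)


def write_fasta(path, records):
    path.write_text("".join(f">{n}\n{s}\n" for n, s in records))


def write_stockholm(path, records):
    body = "\n".join(f"{n}  {s}" for n, s in records)
    path.write_text(f"# STOCKHOLM 1.0\n{body}\n//\n")


def write_clustal(path, records):
    body = "\n".join(f"{n}      {s}" for n, s in records)
    path.write_text(f"CLUSTAL W (1.83) multiple sequence alignment\n\n{body}\n")


class TestReadAlignment:
    RECORDS = [("seq1", "ACGU-"), ("seq2", "AC-GU")]

    @pytest.mark.parametrize(
        "writer,fmt",
        [(write_fasta, "fasta"), (write_stockholm, "stockholm"),
         (write_clustal, "clustal")],
    )
    def test_parses_all_dialects(self, tmp_path, writer, fmt):
        path = tmp_path / f"aln.{fmt}"
        writer(path, self.RECORDS)
        aln = read_alignment(path, fmt)
        assert aln.records == tuple(self.RECORDS)
        assert aln.length == 5

    def test_normalizes_case_and_dna(self, tmp_path):
        path = tmp_path / "aln.fasta"
        write_fasta(path, [("a", "acgt"), ("b", "A.G-")])
        aln = read_alignment(path, "fasta")
        assert aln.seq("a") == "ACGU"
        assert aln.seq("b") == "A-G-"  # '.' reads as gap

    def test_ragged_rows_name_the_offender(self, tmp_path):
        path = tmp_path / "aln.fasta"
        write_fasta(path, [("ok", "ACGUA"), ("bad", "ACGUAG")])
        with pytest.raises(AlignmentFormatError, match="bad"):
            read_alignment(path, "fasta")

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "aln.fasta"
        path.write_text("")
        with pytest.raises(AlignmentFormatError):
            read_alignment(path, "fasta")

    def test_unknown_format_rejected(self, tmp_path):
        path = tmp_path / "aln.phy"
        path.write_text("x")
        with pytest.raises(ParameterError):
            read_alignment(path, "phylip")


class TestReduceRedundancy:
    def test_identical_pair_collapses(self):
        aln = Alignment((("a", "ACGU"), ("b", "ACGU")))
        assert reduce_redundancy(aln, 0.9).names == ("a",)

    def test_disjoint_pair_kept(self):
        aln = Alignment((("a", "ACGU"), ("b", "UGCA")))
        assert reduce_redundancy(aln, 0.9).names == ("a", "b")

    def test_threshold_out_of_range(self):
        aln = Alignment((("a", "ACGU"),))
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ParameterError):
                reduce_redundancy(aln, bad)

    def test_matches_bruteforce_greedy(self):
        # 5 records with a seeded mix of identities; independent greedy scan
        rng = np.random.default_rng(11)
        base = "".join(rng.choice(list("ACGU"), size=30))
        records = [("s0", base)]
        for i in range(1, 5):
            seq = list(base)
            for pos in rng.choice(30, size=rng.integers(1, 15), replace=False):
                seq[pos] = rng.choice([c for c in "ACGU" if c != seq[pos]])
            records.append((f"s{i}", "".join(seq)))
        aln = Alignment(tuple(records))
        threshold = 0.8

        kept = []
        for name, seq in records:
            if all(pairwise_identity(seq, ks) < threshold for _, ks in kept):
                kept.append((name, seq))
        expected = tuple(n for n, _ in kept)
        assert reduce_redundancy(aln, threshold).names == expected

    def test_threshold_one_removes_only_exact_duplicates(self):
        aln = Alignment(
            (("a", "ACGU-"), ("b", "ACGU-"), ("c", "ACGUU"), ("d", "ACGU-"))
        )
        assert reduce_redundancy(aln, 1.0).names == ("a", "c")


class TestConservedCore:
    def test_gapfree_alignment_is_identity(self):
        aln = Alignment((("a", "ACGUACG"), ("b", "UGCAUGC")))
        core = conserved_core(aln, ["a", "b"])
        assert core.columns == tuple(range(7))
        assert core.per_seq["a"] == tuple(range(7))
        assert core.per_seq["b"] == tuple(range(7))

    def test_gap_column_excluded_and_indices_shift(self):
        aln = Alignment((("a", "ACGU"), ("b", "A-GU")))
        core = conserved_core(aln, ["a", "b"])
        assert core.columns == (0, 2, 3)
        assert core.per_seq["a"] == (0, 2, 3)
        assert core.per_seq["b"] == (0, 1, 2)

    def test_empty_core_raises_with_advice(self):
        aln = Alignment((("a", "AC--"), ("b", "--GU")))
        with pytest.raises(EmptyCoreError, match="revise"):
            conserved_core(aln, ["a", "b"])

    def test_matches_bruteforce_column_scan(self):
        rng = np.random.default_rng(5)
        names = [f"s{i}" for i in range(6)]
        length = 40
        rows = {}
        for name in names:
            row = [str(rng.choice(list("ACGU"))) for _ in range(length)]
            for pos in rng.choice(length, size=8, replace=False):
                row[pos] = "-"
            rows[name] = "".join(row)
        aln = Alignment(tuple((n, rows[n]) for n in names))
        try:
            core = conserved_core(aln, names)
        except EmptyCoreError:
            pytest.skip("seeded alignment had no common column")

        expected_cols = tuple(
            c for c in range(length)
            if all(rows[n][c] not in GAP_CHARS for n in names)
        )
        assert core.columns == expected_cols
        for n in names:
            expected_idx = tuple(
                sum(ch not in GAP_CHARS for ch in rows[n][:c])
                for c in expected_cols
            )
            assert core.per_seq[n] == expected_idx

    def test_selected_must_be_present_and_plural(self):
        aln = Alignment((("a", "ACGU"), ("b", "ACGU")))
        with pytest.raises(ParameterError):
            conserved_core(aln, ["a"])
        with pytest.raises(ParameterError):
            conserved_core(aln, ["a", "zz"])

    def test_roundtrip_tsv(self, tmp_path):
        aln = Alignment((("a", "ACGU"), ("b", "A-GU")))
        core = conserved_core(aln, ["a", "b"])
        path = tmp_path / "core.tsv"
        core.to_tsv(path)
        assert CoreMap.from_tsv(path) == core


# -- property tests -----------------------------------------------------------

@st.composite
def gapped_alignments(draw):
    n_seq = draw(st.integers(3, 6))
    length = draw(st.integers(6, 20))
    rows = []
    for i in range(n_seq):
        row = draw(
            st.lists(
                st.sampled_from("ACGU-"), min_size=length, max_size=length
            )
        )
        rows.append((f"s{i}", "".join(row)))
    return Alignment(tuple(rows))


@given(gapped_alignments(), st.randoms(use_true_random=False))
@settings(max_examples=60, deadline=None)
def test_core_is_order_invariant_in_selection(aln, rnd):
    names = list(aln.names)
    shuffled = names[:]
    rnd.shuffle(shuffled)
    try:
        a = conserved_core(aln, names)
    except EmptyCoreError:
        with pytest.raises(EmptyCoreError):
            conserved_core(aln, shuffled)
        return
    b = conserved_core(aln, shuffled)
    assert a.columns == b.columns
    assert a.per_seq == b.per_seq


@given(gapped_alignments())
@settings(max_examples=60, deadline=None)
def test_adding_a_sequence_never_enlarges_the_core(aln):
    names = list(aln.names)
    try:
        smaller = conserved_core(aln, names[:-1]) if len(names) > 2 else None
        full = conserved_core(aln, names)
    except EmptyCoreError:
        return
    if smaller is not None:
        assert set(full.columns) <= set(smaller.columns)


@given(gapped_alignments())
@settings(max_examples=60, deadline=None)
def test_per_seq_indices_recover_the_column_characters(aln):
    try:
        core = conserved_core(aln, list(aln.names))
    except EmptyCoreError:
        return
    for name in aln.names:
        gapped = aln.seq(name)
        ungapped = aln.ungapped(name)
        for col, ridx in zip(core.columns, core.per_seq[name]):
            assert ungapped[ridx] == gapped[col]
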