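"""Alignment I/O, trimming, concatenation and column statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribopart.seqio import (
    Alignment,
    AlignmentError,
    CharacterSet,
    PartitionScheme,
    alignment_statistics,
    concatenate,
    count_parsimony_informative,
    exclude_columns,
    read_alignment,
    strip_flanking_gaps,
    to_nexus,
    write_alignment,
)


class TestAlignmentConstruction:
    def test_rejects_ragged_rows(self):
        with pytest.raises(AlignmentError, match="beta"):
            Alignment(["alpha", "beta"], ["ACGT", "ACG"])

    def test_rejects_duplicate_labels(self):
        with pytest.raises(AlignmentError, match="duplicate"):
            Alignment(["a", "a"], ["ACGT", "ACGT"])

    def test_rejects_unknown_symbol_with_column(self):
        with pytest.raises(AlignmentError, match="column 2"):
            Alignment(["a", "b"], ["ACGT", "AC!T"])

    def test_accepts_iupac_gap_missing(self):
        a = Alignment(["a", "b"], ["RYSWKM", "BDHVN?"])
        assert a.length == 6


class TestReadWrite:
    def test_fasta_parse(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">t1 extra comment\nACGT\n>t2\nAC-T\n")
        a = read_alignment(p, "fasta")
        assert a.taxa == ["t1", "t2"]
        assert a.row("t2") == "AC-T"
        assert (a.matrix == "-").sum() == 1

    def test_empty_fasta_errors(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(AlignmentError):
            read_alignment(p, "fasta")

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_alignment(tmp_path / "nope.fa", "fasta")

    def test_nexus_charset_conversion(self, tmp_path):
        # the NEXUS convention "1-659" (1-based inclusive) becomes [0, 659)
        seqs = {"t1": "A" * 700, "t2": "C" * 700}
        nex = "#NEXUS\nbegin data;\ndimensions ntax=2 nchar=700;\n"
        nex += "format datatype=dna gap=- missing=?;\nmatrix\n"
        for t, s in seqs.items():
            nex += f"{t}  {s}\n"
        nex += ";\nend;\nbegin sets;\ncharset ITS1 = 1-659;\nend;\n"
        p = tmp_path / "a.nex"
        p.write_text(nex)
        a = read_alignment(p, "nexus")
        assert a.charsets["ITS1"].intervals == ((0, 659),)

    def test_nexus_round_trip_is_exact(self, tmp_path, toy_alignment):
        toy_alignment.charsets["left"] = CharacterSet("left", ((0, 4),))
        toy_alignment.charsets["right"] = CharacterSet("right", ((4, 8),))
        p = tmp_path / "rt.nex"
        write_alignment(toy_alignment, p, "nexus")
        back = read_alignment(p, "nexus")
        assert back == toy_alignment


class TestStripFlankingGaps:
    def test_identity_without_terminal_gaps(self, toy_alignment):
        out = strip_flanking_gaps(toy_alignment)
        assert out == toy_alignment

    def test_leading_gap_becomes_missing(self):
        a = Alignment(["a", "b"], ["--ACG", "TTACG"])
        out = strip_flanking_gaps(a)
        assert out.row("a") == "??ACG"
        assert out.length == 5

    def test_shared_leading_gaps_drop_columns(self):
        a = Alignment(["a", "b"], ["--ACG", "--ACG"])
        out = strip_flanking_gaps(a)
        assert out.length == 3
        assert out.row("a") == "ACG"

    def test_all_gap_alignment_errors(self):
        a = Alignment(["a", "b"], ["----", "----"])
        with pytest.raises(AlignmentError):
            strip_flanking_gaps(a)

    def test_idempotent(self):
        a = Alignment(["a", "b", "c"], ["--AC-G?", "TTAC-GG", "T-AC-G-"])
        once = strip_flanking_gaps(a)
        twice = strip_flanking_gaps(once)
        assert once == twice

    def test_interior_gaps_untouched(self):
        a = Alignment(["a", "b"], ["A--CG", "ATTCG"])
        assert strip_flanking_gaps(a).row("a") == "A--CG"


class TestConcatenate:
    def test_single_alignment_identity(self, toy_alignment):
        out, scheme = concatenate([toy_alignment], ["only"])
        assert out.taxa == toy_alignment.taxa
        assert (out.matrix == toy_alignment.matrix).all()
        assert scheme.parts[0][0].name == "only"

    def test_disjoint_taxa_filled_with_missing(self):
        a = Alignment(["x"], ["ACGT"])
        b = Alignment(["y"], ["TTTT"])
        out, _ = concatenate([a, b], ["A", "B"])
        assert out.row("x") == "ACGT????"
        assert out.row("y") == "????TTTT"

    def test_block_lengths_add_up(self):
        # three ribosomal-locus-sized blocks concatenate to their sum
        blocks = [
            Alignment(["t1", "t2"], ["A" * n, "C" * n]) for n in (1018, 1362, 1504)
        ]
        out, scheme = concatenate(blocks, ["SSU", "ITS", "LSU"])
        assert out.length == 3884
        assert scheme.charsets["ITS"].intervals == ((1018, 2380),)

    def test_duplicate_names_error(self, toy_alignment):
        with pytest.raises(AlignmentError, match="duplicate"):
            concatenate([toy_alignment, toy_alignment], ["x", "x"])


class TestExcludeColumns:
    def test_empty_charset_is_identity(self, toy_alignment):
        out = exclude_columns(toy_alignment, CharacterSet("none", ()))
        assert out == toy_alignment

    def test_excluding_everything_errors(self, toy_alignment):
        with pytest.raises(AlignmentError):
            exclude_columns(toy_alignment, CharacterSet("all", ((0, 8),)))

    def test_out_of_range_errors(self, toy_alignment):
        with pytest.raises(AlignmentError):
            exclude_columns(toy_alignment, CharacterSet("far", ((5, 99),)))

    def test_exclusion_complements_concatenation(self):
        blocks = [
            Alignment(["t1", "t2"], [s * n, s2 * n])
            for n, s, s2 in ((5, "A", "C"), (7, "G", "T"), (4, "C", "A"))
        ]
        out, scheme = concatenate(blocks, ["SSU", "ITS", "LSU"])
        reduced = exclude_columns(out, scheme.charsets["ITS"])
        assert reduced.length == 9
        assert reduced.row("t1") == "A" * 5 + "C" * 4
        # surviving charsets re-indexed
        assert reduced.charsets["LSU"].intervals == ((5, 9),)
        assert "ITS" not in reduced.charsets


class TestParsimonyInformative:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ("AACC", 1),  # two states, twice each
            ("AAAC", 0),  # singleton state
            ("AA--CC", 1),  # gaps excluded from the tally
            ("AANRCC", 1),  # ambiguity excluded
            ("ACGT", 0),  # all singletons
        ],
    )
    def test_single_column_definition(self, column, expected):
        a = Alignment([f"t{i}" for i in range(len(column))], list(column))
        assert count_parsimony_informative(a) == expected

    def test_additive_over_disjoint_charsets(self, toy_alignment):
        left = CharacterSet("l", ((0, 4),))
        right = CharacterSet("r", ((4, 8),))
        assert count_parsimony_informative(toy_alignment) == count_parsimony_informative(
            toy_alignment, left
        ) + count_parsimony_informative(toy_alignment, right)

    @given(perm=st.permutations(range(4)))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_taxon_reordering(self, perm):
        rows = ["ACGTACGT", "ACGTACGA", "AC--ACGT", "ACGTTCGT"]
        taxa = ["a", "b", "c", "d"]
        base = count_parsimony_informative(Alignment(taxa, rows))
        shuffled = count_parsimony_informative(
            Alignment([taxa[i] for i in perm], [rows[i] for i in perm])
        )
        assert base == shuffled

    def test_statistics_summary(self, toy_alignment):
        toy_alignment.charsets["all"] = CharacterSet("all", ((0, 8),))
        stats = alignment_statistics(toy_alignment)
        assert stats["length"] == 8
        assert stats["charsets"]["all"]["parsimony_informative"] == stats["parsimony_informative"]


class TestPartitionScheme:
    def test_overlapping_parts_rejected(self):
        a = CharacterSet("a", ((0, 5),))
        b = CharacterSet("b", ((4, 8),))
        with pytest.raises(AlignmentError):
            PartitionScheme("bad", ((a, "nuc"), (b, "nuc")))

    def test_covers(self):
        a = CharacterSet("a", ((0, 5),))
        b = CharacterSet("b", ((5, 8),))
        s = PartitionScheme("ok", ((a, "nuc"), (b, "nuc")))
        assert s.covers(8) and not s.covers(9)
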