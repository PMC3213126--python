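"""Alignment I/O, partition definitions and alignment statistics.

The central container is :class:`Alignment`, a rectangular taxa x columns
character matrix over the DNA alphabet extended with IUPAC ambiguity codes,
the gap symbol ``-`` and the missing symbol ``?``.  Column sets are addressed
through :class:`CharacterSet` (0-based, half-open intervals internally; the
NEXUS convention of 1-based inclusive ranges is converted exactly once, at the
I/O boundary).  A :class:`PartitionScheme` binds named, disjoint character
sets to substitution-model tags and is the object the regime catalog and the
likelihood engine share.

Preprocessing implemented here: conversion of per-taxon terminal
(leading/trailing) gap runs to missing data — unsequenced flanks are absence
of data, not indel events — and generic column exclusion used to build the
reduced datasets (e.g. "without the ITS region").
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Nexus import Nexus

DNA_STATES = "ACGT"
AMBIGUITY = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
GAP = "-"
MISSING = "?"
VALID_SYMBOLS = frozenset(DNA_STATES) | set(AMBIGUITY) | {GAP, MISSING}


class AlignmentError(ValueError):
    """Malformed alignment, charset or partition input."""


@dataclass(frozen=True)
class CharacterSet:
    """A named set of alignment columns as sorted, disjoint half-open intervals."""

    name: str
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self):
        ivs = tuple((int(a), int(b)) for a, b in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        last = -1
        for a, b in ivs:
            if a < 0 or b <= a:
                raise AlignmentError(f"charset {self.name!r}: bad interval [{a},{b})")
            if a < last:
                raise AlignmentError(f"charset {self.name!r}: intervals overlap or are unsorted")
            last = b

    @classmethod
    def from_columns(cls, name: str, columns) -> "CharacterSet":
        """Build from an unordered iterable of 0-based column indices."""
        cols = np.unique(np.asarray(list(columns), dtype=int))
        if cols.size == 0:
            return cls(name, ())
        breaks = np.nonzero(np.diff(cols) > 1)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [cols.size - 1]])
        return cls(name, tuple((int(cols[s]), int(cols[e]) + 1) for s, e in zip(starts, ends)))

    def columns(self) -> np.ndarray:
        if not self.intervals:
            return np.empty(0, dtype=int)
        return np.concatenate([np.arange(a, b) for a, b in self.intervals])

    @property
    def n_columns(self) -> int:
        return sum(b - a for a, b in self.intervals)

    def within(self, length: int) -> bool:
        return all(b <= length for _, b in self.intervals)

    def to_nexus(self) -> str:
        """1-based inclusive ``a-b`` ranges, single columns as bare numbers."""
        parts = []
        for a, b in self.intervals:
            parts.append(str(a + 1) if b == a + 1 else f"{a + 1}-{b}")
        return f"charset {self.name} = {' '.join(parts)};"


@dataclass(frozen=True)
class PartitionScheme:
    """Ordered (CharacterSet, model-spec tag) pairs with mutually disjoint columns."""

    name: str
    parts: tuple[tuple[CharacterSet, str], ...]

    def __post_init__(self):
        object.__setattr__(self, "parts", tuple(self.parts))
        seen: set[int] = set()
        for cs, _tag in self.parts:
            cols = set(cs.columns().tolist())
            if cols & seen:
                raise AlignmentError(f"partition scheme {self.name!r}: overlapping charsets")
            seen |= cols

    @property
    def charsets(self) -> dict[str, CharacterSet]:
        return {cs.name: cs for cs, _ in self.parts}

    def covers(self, length: int) -> bool:
        n = sum(cs.n_columns for cs, _ in self.parts)
        return n == length and all(cs.within(length) for cs, _ in self.parts)


class Alignment:
    """Rectangular multiple sequence alignment over DNA + gap/ambiguity/missing.

    Parameters
    ----------
    taxa : sequence of str
        Unique taxon labels, order preserved.
    rows : sequence of str
        One symbol string per taxon; all equal length >= 1.
    charsets : dict, optional
        Named :class:`CharacterSet` column annotations riding along with the
        matrix (populated from NEXUS SETS blocks).
    """

    def __init__(self, taxa, rows, charsets: dict[str, CharacterSet] | None = None):
        taxa = list(taxa)
        if len(set(taxa)) != len(taxa):
            dup = sorted({t for t in taxa if taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxon labels: {dup}")
        if not taxa:
            raise AlignmentError("alignment has no taxa")
        rows = [str(r).upper() for r in rows]
        if len(rows) != len(taxa):
            raise AlignmentError("taxa/rows length mismatch")
        length = len(rows[0])
        for t, r in zip(taxa, rows):
            if len(r) != length:
                raise AlignmentError(f"ragged alignment: taxon {t!r} has length {len(r)} != {length}")
        if length == 0:
            raise AlignmentError("alignment has zero columns")
        mat = np.array([list(r) for r in rows], dtype="U1")
        bad = ~np.isin(mat, list(VALID_SYMBOLS))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise AlignmentError(
                f"unknown symbol {mat[i, j]!r} for taxon {taxa[i]!r} at column {j}"
            )
        self.taxa: list[str] = taxa
        self.matrix: np.ndarray = mat
        self.charsets: dict[str, CharacterSet] = dict(charsets or {})
        for cs in self.charsets.values():
            if not cs.within(length):
                raise AlignmentError(f"charset {cs.name!r} exceeds alignment length {length}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> str:
        return "".join(self.matrix[self.taxa.index(taxon)])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.taxa == other.taxa
            and self.matrix.shape == other.matrix.shape
            and bool((self.matrix == other.matrix).all())
            and self.charsets == other.charsets
        )

    def __repr__(self) -> str:
        return f"<Alignment {self.n_taxa} taxa x {self.length} columns, {len(self.charsets)} charsets>"


# ---------------------------------------------------------------------------
# reading / writing


def read_alignment(path, format: str = "fasta") -> Alignment:
    """Read a FASTA or NEXUS alignment; NEXUS SETS-block charsets are attached.

    FASTA labels are the header up to the first whitespace.  NEXUS charset
    ranges (1-based inclusive) become 0-based half-open intervals.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"no sequences in {path}")
        return Alignment([r.id for r in records], [str(r.seq) for r in records])
    if format == "nexus":
        nex = Nexus.Nexus(str(path))
        if not nex.matrix:
            raise AlignmentError(f"no data matrix in {path}")
        taxa = list(nex.unaltered_taxlabels) or list(nex.matrix.keys())
        rows = [str(nex.matrix[t]) for t in taxa]
        charsets = {
            name: CharacterSet.from_columns(name, cols)
            for name, cols in nex.charsets.items()
        }
        return Alignment(taxa, rows, charsets)
    raise ValueError(f"unknown format {format!r}")


def write_alignment(aln: Alignment, path, format: str = "nexus") -> None:
    path = Path(path)
    if format == "fasta":
        with path.open("w") as fh:
            for t, row in zip(aln.taxa, aln.matrix):
                fh.write(f">{t}\n{''.join(row)}\n")
        return
    if format == "nexus":
        path.write_text(to_nexus(aln))
        return
    raise ValueError(f"unknown format {format!r}")


def to_nexus(aln: Alignment, datatype: str = "dna") -> str:
    buf = io.StringIO()
    buf.write("#NEXUS\n\nbegin data;\n")
    buf.write(f"    dimensions ntax={aln.n_taxa} nchar={aln.length};\n")
    buf.write(f"    format datatype={datatype} gap=- missing=?;\n    matrix\n")
    width = max(len(t) for t in aln.taxa) + 2
    for t, row in zip(aln.taxa, aln.matrix):
        label = f"'{t}'" if any(c.isspace() for c in t) else t
        buf.write(f"    {label:<{width}}{''.join(row)}\n")
    buf.write("    ;\nend;\n")
    if aln.charsets:
        buf.write("\nbegin sets;\n")
        for cs in aln.charsets.values():
            buf.write(f"    {cs.to_nexus()}\n")
        buf.write("end;\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# preprocessing


def strip_flanking_gaps(aln: Alignment) -> Alignment:
    """Convert per-taxon terminal gap runs to missing data.

    For every taxon the maximal gap run touching column 0 and the maximal run
    touching the last column are rewritten to ``?`` (a run may already abut
    missing ``?`` flanks, which extend it).  Columns left missing in every
    taxon are then deleted; interior gaps are untouched.
    """
    mat = aln.matrix.copy()
    n, L = mat.shape
    for i in range(n):
        j = 0
        while j < L and mat[i, j] in (GAP, MISSING):
            mat[i, j] = MISSING
            j += 1
        j = L - 1
        while j >= 0 and mat[i, j] in (GAP, MISSING):
            mat[i, j] = MISSING
            j -= 1
    keep = ~(mat == MISSING).all(axis=0)
    if not keep.any():
        raise AlignmentError("alignment empty after flanking-gap removal")
    if keep.all():
        out_mat = mat
        charsets = dict(aln.charsets)
    else:
        out_mat = mat[:, keep]
        old_cols = np.nonzero(keep)[0]
        remap = {int(c): i for i, c in enumerate(old_cols)}
        charsets = {
            name: CharacterSet.from_columns(
                name, [remap[c] for c in cs.columns().tolist() if c in remap]
            )
            for name, cs in aln.charsets.items()
        }
    return Alignment(aln.taxa, ["".join(r) for r in out_mat], charsets)


def concatenate(alignments, charset_names) -> tuple[Alignment, PartitionScheme]:
    """Concatenate alignments into a supermatrix over the union of taxa.

    Blocks absent for a taxon are filled with ``?``.  The returned scheme has
    one charset per input block, in input order, tagged ``"nuc"``.
    """
    alignments = list(alignments)
    charset_names = list(charset_names)
    if not alignments:
        raise AlignmentError("nothing to concatenate")
    if len(charset_names) != len(alignments):
        raise AlignmentError("need one charset name per alignment")
    if len(set(charset_names)) != len(charset_names):
        raise AlignmentError(f"duplicate charset names: {charset_names}")
    taxa: list[str] = []
    for a in alignments:
        for t in a.taxa:
            if t not in taxa:
                taxa.append(t)
    rows = {t: [] for t in taxa}
    parts = []
    offset = 0
    for name, a in zip(charset_names, alignments):
        for t in taxa:
            rows[t].append(a.row(t) if t in a.taxa else MISSING * a.length)
        cs = CharacterSet(name, ((offset, offset + a.length),))
        parts.append((cs, "nuc"))
        offset += a.length
    out = Alignment(taxa, ["".join(rows[t]) for t in taxa], {cs.name: cs for cs, _ in parts})
    return out, PartitionScheme("concatenated", tuple(parts))


def exclude_columns(aln: Alignment, cs: CharacterSet) -> Alignment:
    """Drop the columns of `cs`; attached charsets are re-indexed to the survivors."""
    if not cs.within(aln.length):
        raise AlignmentError(f"charset {cs.name!r} out of range for length {aln.length}")
    drop = np.zeros(aln.length, dtype=bool)
    drop[cs.columns()] = True
    keep = ~drop
    if not keep.any():
        raise AlignmentError("exclusion removes every column")
    old_cols = np.nonzero(keep)[0]
    remap = {int(c): i for i, c in enumerate(old_cols)}
    charsets = {}
    for name, other in aln.charsets.items():
        cols = [remap[c] for c in other.columns().tolist() if c in remap]
        if cols:
            charsets[name] = CharacterSet.from_columns(name, cols)
    return Alignment(aln.taxa, ["".join(r) for r in aln.matrix[:, keep]], charsets)


# ---------------------------------------------------------------------------
# statistics


def count_parsimony_informative(aln: Alignment, cs: CharacterSet | None = None) -> int:
    """Number of parsimony-informative columns.

    A column is informative when at least two distinct unambiguous nucleotide
    states are each present in at least two taxa; gaps, ``?`` and IUPAC
    ambiguity codes are excluded from the tally.
    """
    mat = aln.matrix if cs is None else aln.matrix[:, cs.columns()]
    count = 0
    for j in range(mat.shape[1]):
        col = mat[:, j]
        states, freqs = np.unique(col[np.isin(col, list(DNA_STATES))], return_counts=True)
        if (freqs >= 2).sum() >= 2:
            count += 1
    return count


def alignment_statistics(aln: Alignment) -> dict:
    """Length / variability summary overall and per attached charset."""
    out = {
        "n_taxa": aln.n_taxa,
        "length": aln.length,
        "parsimony_informative": count_parsimony_informative(aln),
    }
    per = {}
    for name, cs in aln.charsets.items():
        per[name] = {
            "length": cs.n_columns,
            "parsimony_informative": count_parsimony_informative(aln, cs),
        }
    out["charsets"] = per
    return out
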