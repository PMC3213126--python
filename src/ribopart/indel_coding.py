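"""Simple indel coding (SIC): recode alignment gaps as binary characters.

Each distinct maximal interior gap extent observed in the alignment becomes
one presence/absence character.  A taxon scores 1 when it carries a gap of
exactly that extent, ``?`` (inapplicable) when one of its gaps strictly
contains the extent, and 0 otherwise — including partial, non-nested overlap.
Missing ``?`` nucleotide cells (unsequenced flanks after trimming) never open
or close a gap run.  Characters are ordered by (start, end) so NEXUS emission
is deterministic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .seqio import GAP, Alignment

STATE_ABSENT = "0"
STATE_PRESENT = "1"
STATE_INAPPLICABLE = "?"


@dataclass(frozen=True)
class IndelEvent:
    """A distinct gap extent: 0-based half-open columns plus its supporting taxa."""

    start: int
    end: int
    supporting_taxa: frozenset[str]

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad gap extent [{self.start},{self.end})")
        if not self.supporting_taxa:
            raise ValueError("gap extent with no supporting taxon")

    @property
    def extent(self) -> tuple[int, int]:
        return (self.start, self.end)


class BinaryIndelMatrix:
    """Taxa x indel characters with cells in {0, 1, ?}."""

    def __init__(self, taxa, events, cells):
        self.taxa: list[str] = list(taxa)
        self.events: list[IndelEvent] = list(events)
        self.cells: np.ndarray = np.asarray(cells, dtype="U1")
        if self.cells.shape != (len(self.taxa), len(self.events)):
            raise ValueError("cell matrix shape inconsistent with taxa x characters")
        for k, ev in enumerate(self.events):
            if not (self.cells[:, k] == STATE_PRESENT).any():
                raise ValueError(f"character {ev.extent} has no 1 cell")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.events)

    def __repr__(self) -> str:
        return f"<BinaryIndelMatrix {self.n_taxa} taxa x {self.n_characters} indel characters>"


def _gap_runs(row: np.ndarray) -> list[tuple[int, int]]:
    # maximal runs of '-' in one row; '?' terminates a run (missing flanks are not indels)
    runs = []
    start = None
    for j, c in enumerate(row):
        if c == GAP:
            if start is None:
                start = j
        else:
            if start is not None:
                runs.append((start, j))
                start = None
    if start is not None:
        runs.append((start, len(row)))
    return runs


def extract_gap_extents(aln: Alignment) -> list[IndelEvent]:
    """One IndelEvent per distinct maximal gap extent, sorted by (start, end).

    Terminal gaps should already have been converted to missing data
    (``strip_flanking_gaps``); any remaining run is treated as an indel.
    """
    support: dict[tuple[int, int], set[str]] = {}
    for taxon, row in zip(aln.taxa, aln.matrix):
        for extent in _gap_runs(row):
            support.setdefault(extent, set()).add(taxon)
    return [
        IndelEvent(s, e, frozenset(support[(s, e)]))
        for s, e in sorted(support)
    ]


def sic_encode(aln: Alignment) -> BinaryIndelMatrix:
    """Encode every distinct gap extent as one binary character.

    Scoring per taxon and extent [s, e): 1 if the taxon has a gap run of
    exactly that extent; '?' if one of its runs strictly contains [s, e);
    0 otherwise (no gap there, or only partial overlap).
    """
    events = extract_gap_extents(aln)
    cells = np.full((aln.n_taxa, len(events)), STATE_ABSENT, dtype="U1")
    runs_per_taxon = [_gap_runs(row) for row in aln.matrix]
    for k, ev in enumerate(events):
        for i, runs in enumerate(runs_per_taxon):
            for s, e in runs:
                if (s, e) == ev.extent:
                    cells[i, k] = STATE_PRESENT
                    break
                if s <= ev.start and ev.end <= e and (s, e) != ev.extent:
                    cells[i, k] = STATE_INAPPLICABLE
                    break
    return BinaryIndelMatrix(aln.taxa, events, cells)


def indel_matrix_stats(m: BinaryIndelMatrix) -> dict:
    """Character count and parsimony-informative count over {0,1} ('?' ignored)."""
    n_pi = 0
    for k in range(m.n_characters):
        col = m.cells[:, k]
        n0 = int((col == STATE_ABSENT).sum())
        n1 = int((col == STATE_PRESENT).sum())
        if n0 >= 2 and n1 >= 2:
            n_pi += 1
    return {"n_characters": m.n_characters, "n_parsimony_informative": n_pi}


def to_nexus(m: BinaryIndelMatrix) -> str:
    """Binary partition as a standard-datatype NEXUS DATA block."""
    buf = io.StringIO()
    buf.write("#NEXUS\n\nbegin data;\n")
    buf.write(f"    dimensions ntax={m.n_taxa} nchar={m.n_characters};\n")
    buf.write('    format datatype=standard symbols="01" missing=?;\n    matrix\n')
    width = max(len(t) for t in m.taxa) + 2
    for i, t in enumerate(m.taxa):
        label = f"'{t}'" if any(c.isspace() for c in t) else t
        buf.write(f"    {label:<{width}}{''.join(m.cells[i])}\n")
    buf.write("    ;\nend;\n")
    buf.write("\n[character extents, 1-based inclusive columns of the source alignment]\n")
    for ev in m.events:
        buf.write(f"[  indel_{ev.start + 1}_{ev.end}  =  {ev.start + 1}-{ev.end}  ]\n")
    return buf.getvalue()
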