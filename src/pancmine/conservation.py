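"""Sliding-window conservation scoring and nucleotide motif annotation.

Implements the VISTA-style match criterion used for cross-species
comparison of a locus: percent identity in a sliding window of alignment
columns (default 50 bp), with windows at or above the threshold (default
70%, inclusive) merged into conserved segments reported in the ungapped
coordinates of a reference row.  Gap and N columns count as mismatches —
the conservative choice.

Motif scanning covers IUPAC patterns on both strands.  The bundled default
set holds the two SMAD binding elements with literature-stated sequences:
the canonical CAGAC box and the 5GC SBE, GGC(GC)(CG), expanded to the
two words GGCGC and GGCCG.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import AlignIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

#: Default motif set: (name, IUPAC pattern).  The 5GC SBE alternation
#: GGC(GC)(CG) is carried as its two literal expansions under one name.
SBE_MOTIFS: list[tuple[str, str]] = [
    ("SBE_CAGAC", "CAGAC"),
    ("SBE_5GC", "GGCGC"),
    ("SBE_5GC", "GGCCG"),
]

_VALID_ROW = re.compile(r"^[ACGTNacgtn\-]+$")


@dataclass
class GappedAlignment:
    """A gapped multiple alignment; one row carries reference coordinates."""

    names: list[str]
    rows: list[str]
    reference_row: int = 0

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in length")
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least two rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]
        for name, row in zip(self.names, self.rows):
            if not _VALID_ROW.match(row):
                raise ValueError(f"row {name!r} has non-IUPAC/non-gap characters")
        ref = self.rows[self.reference_row]
        if ref.count("-") == len(ref):
            raise ValueError("reference row is all gaps")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def reference_positions(self) -> np.ndarray:
        """1-based ungapped reference position at each column (0 before first base)."""
        ref = np.frombuffer(self.rows[self.reference_row].encode(), dtype="S1")
        return np.cumsum(ref != b"-")


def read_aligned_fasta(
    path: str | Path, reference: str | None = None
) -> GappedAlignment:
    """Load an aligned FASTA; ``reference`` selects the coordinate row by name."""
    aln = AlignIO.read(str(path), "fasta")
    names = [rec.id for rec in aln]
    rows = [str(rec.seq) for rec in aln]
    ref_idx = 0
    if reference is not None:
        if reference not in names:
            raise ValueError(f"reference row {reference!r} not in {names}")
        ref_idx = names.index(reference)
    return GappedAlignment(names, rows, ref_idx)


def window_identity(
    aln: GappedAlignment,
    row_pair: tuple[int, int] = (0, 1),
    window: int = 50,
) -> np.ndarray:
    """Fraction of identical columns in each sliding window (step 1 column).

    A column matches only when both rows carry the same unambiguous
    nucleotide; any gap or N counts as a mismatch.  If the alignment is
    shorter than the window a single truncated window is scored (and a
    warning logged).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    i, j = row_pair
    a = np.frombuffer(aln.rows[i].encode(), dtype="S1")
    b = np.frombuffer(aln.rows[j].encode(), dtype="S1")
    match = (a == b) & np.isin(a, np.array([b"A", b"C", b"G", b"T"]))
    if len(match) < window:
        log.warning(
            "alignment (%d columns) shorter than window (%d); single truncated window",
            len(match), window,
        )
        return np.array([match.mean()])
    csum = np.concatenate(([0], np.cumsum(match)))
    return (csum[window:] - csum[:-window]) / window


@dataclass(frozen=True)
class ConservedSegment:
    """A merged run of qualifying windows, in reference ungapped coordinates."""

    start: int  # 1-based inclusive
    end: int
    mean_identity: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("segment end < start")
        if not 0.0 <= self.mean_identity <= 1.0:
            raise ValueError("mean_identity outside [0,1]")


def call_conserved(
    aln: GappedAlignment,
    row_pair: tuple[int, int] = (0, 1),
    threshold: float = 0.70,
    window: int = 50,
    identities: np.ndarray | None = None,
) -> list[ConservedSegment]:
    """Merge windows with identity >= ``threshold`` into conserved segments.

    Overlapping qualifying windows are merged in alignment-column space and
    each merged span is reported over the reference row's ungapped
    coordinates with its column-level mean identity.  The threshold is
    inclusive (a 35/50 window qualifies at 0.70; 34/50 does not).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    if identities is None:
        identities = window_identity(aln, row_pair, window)
    width = min(window, aln.n_columns)
    qualifying = np.flatnonzero(np.asarray(identities) >= threshold)
    if len(qualifying) == 0:
        return []
    i, j = row_pair
    a = np.frombuffer(aln.rows[i].encode(), dtype="S1")
    b = np.frombuffer(aln.rows[j].encode(), dtype="S1")
    match = (a == b) & np.isin(a, np.array([b"A", b"C", b"G", b"T"]))
    ref = np.frombuffer(aln.rows[aln.reference_row].encode(), dtype="S1")
    ref_pos = np.cumsum(ref != b"-")  # 1-based position at or before each column

    # merge overlapping qualifying windows in column space
    spans: list[list[int]] = []  # [start_col, end_col] inclusive
    for w in qualifying:
        s, e = int(w), int(w) + width - 1
        if spans and s <= spans[-1][1] + 1:
            spans[-1][1] = max(spans[-1][1], e)
        else:
            spans.append([s, e])

    segments = []
    for s, e in spans:
        cols = slice(s, e + 1)
        non_gap = ref[cols] != b"-"
        if not non_gap.any():
            continue  # span lies entirely in a reference gap
        first = s + int(np.argmax(non_gap))
        last = e - int(np.argmax(non_gap[::-1]))
        segments.append(
            ConservedSegment(
                start=int(ref_pos[first]),
                end=int(ref_pos[last]),
                mean_identity=float(match[cols].mean()),
            )
        )
    return segments


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    pattern: str
    start: int  # 1-based, plus-strand coordinates
    strand: str  # '+' or '-'
    matched_text: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.start < 1:
            raise ValueError("start must be >= 1")
        if len(self.matched_text) != len(self.pattern):
            raise ValueError("matched_text length != pattern length")


def _iupac_regex(pattern: str) -> str:
    try:
        return "".join(IUPAC[c] for c in pattern.upper())
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC character {exc.args[0]!r} in {pattern!r}") from exc


def scan_motifs(
    seq: str,
    motifs: Sequence[tuple[str, str]] = tuple(SBE_MOTIFS),
    both_strands: bool = True,
) -> list[MotifHit]:
    """All (overlapping) IUPAC motif matches in ``seq``.

    Minus-strand hits are found by matching the reverse complement of each
    pattern against the plus strand; coordinates and matched_text are always
    reported in plus-strand space.  Sorted by (start, strand, motif_name).
    """
    seq = seq.upper()
    hits = []
    for name, pattern in motifs:
        searches = [("+", _iupac_regex(pattern))]
        if both_strands:
            rc = str(Seq(pattern).reverse_complement())
            searches.append(("-", _iupac_regex(rc)))
        for strand, rx in searches:
            for m in re.finditer(f"(?=({rx}))", seq):
                hits.append(
                    MotifHit(
                        motif_name=name,
                        pattern=pattern,
                        start=m.start() + 1,
                        strand=strand,
                        matched_text=m.group(1),
                    )
                )
    hits.sort(key=lambda h: (h.start, h.strand, h.motif_name))
    return hits
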