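"""Genomic coordinate primitives.

Coordinate convention
---------------------
User-facing coordinates are 1-based; spans are end-EXCLUSIVE, so
``span_length(region) == region.end - region.start``.  This convention is
chosen because the MUC5B-promoter pancRNA locus it was built around prints a
transcript at chr11:1,218,530–1,220,242 with a length of 1712 nt, which is
only self-consistent under an end-exclusive reading.  Internal arrays are
0-based half-open; index 0 of a depth vector corresponds to ``region.start``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


@dataclass(frozen=True)
class GenomicRegion:
    """A 1-based, end-exclusive interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start (end-exclusive span), got {self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """True if the 1-based position lies inside the region."""
        return self.start <= pos < self.end

    def contains_region(self, other: "GenomicRegion") -> bool:
        return (
            other.chrom == self.chrom
            and other.start >= self.start
            and other.end <= self.end
        )

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """Overlap with another 1-based end-exclusive span."""
        return chrom == self.chrom and start < self.end and end > self.start

    @classmethod
    def from_string(cls, text: str) -> "GenomicRegion":
        """Parse ``chrom:start-end`` (commas in numbers allowed)."""
        m = _REGION_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse region {text!r}; expected chrom:start-end")
        chrom, start, end = m.groups()
        return cls(chrom, int(start.replace(",", "")), int(end.replace(",", "")))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def span_length(region: GenomicRegion) -> int:
    """Length of a region in nucleotides (end − start, end-exclusive)."""
    return region.end - region.start


@dataclass(frozen=True)
class LocusAnnotation:
    """A transcript of interest, its tag SNP and the analysis window around it."""

    transcript: GenomicRegion
    snp_pos: int
    snp_alleles: tuple[str, str]
    analysis_window: GenomicRegion
    exon2_note: str = ""

    def __post_init__(self) -> None:
        if not self.transcript.contains(self.snp_pos):
            raise ValueError(
                f"SNP position {self.snp_pos} lies outside transcript {self.transcript}"
            )
        if not self.analysis_window.contains_region(self.transcript):
            raise ValueError(
                f"transcript {self.transcript} not contained in "
                f"analysis window {self.analysis_window}"
            )


#: The MUC5B-promoter pancRNA locus (GRCh38): the 1712 nt lncRNA AC061979.1
#: overlapping the IPF-associated SNP rs35705950, with the mining window used
#: to filter read pairs.
MUC5B_LOCUS = LocusAnnotation(
    transcript=GenomicRegion("chr11", 1_218_530, 1_220_242),
    snp_pos=1_219_991,
    snp_alleles=("G", "T"),
    analysis_window=GenomicRegion("chr11", 1_202_000, 1_220_500),
    exon2_note="rs35705950 falls on the second nucleotide of putative exon 2",
)
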