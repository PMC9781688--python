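"""CIGAR-aware per-base depth of coverage and splice-junction evidence.

Depth follows the semantics of standard pileup tools: a position gains one
unit of depth for every aligned query base (CIGAR M/=/X) placed on it;
deletions (D) and intron skips (N) consume reference without adding depth;
insertions and clips add nothing.  Depth is stored as int64 so composite
sums over many datasets cannot overflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable

import numpy as np

from pancmine.alignment_io import AlignmentRecord
from pancmine.regions import GenomicRegion, span_length

log = logging.getLogger(__name__)


@dataclass
class CoverageVector:
    """Per-base depth over a region for one dataset; index 0 ↔ region.start."""

    region: GenomicRegion
    depth: np.ndarray
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.shape != (span_length(self.region),):
            raise ValueError(
                f"depth length {self.depth.shape} != span {span_length(self.region)}"
            )
        if (self.depth < 0).any():
            raise ValueError("negative depth")


@dataclass(frozen=True)
class SpliceJunction:
    """An intron inferred from CIGAR N ops: first..last skipped base, 1-based."""

    chrom: str
    intron_start: int
    intron_end: int
    support: int = 1

    def __post_init__(self) -> None:
        if self.intron_end < self.intron_start:
            raise ValueError("intron_end < intron_start")
        if self.support < 1:
            raise ValueError("support must be >= 1")

    @property
    def intron_length(self) -> int:
        return self.intron_end - self.intron_start + 1


def compute_depth(
    records: Iterable[AlignmentRecord],
    region: GenomicRegion,
    dataset_id: str = "",
    count_deletions: bool = False,
) -> CoverageVector:
    """Per-base depth of the records over ``region``.

    Records on other chromosomes are ignored; aligned spans falling outside
    the region are truncated.  ``count_deletions=True`` additionally counts
    D ops as covering (off by default, matching common depth tools).
    """
    n = span_length(region)
    # difference array: +1 at covered-span starts, -1 one past the ends
    diff = np.zeros(n + 1, dtype=np.int64)
    adding = set("M=X") | ({"D"} if count_deletions else set())
    for rec in records:
        if not rec.is_mapped or rec.chrom != region.chrom:
            continue
        if rec.reference_span == 0:
            log.warning("record %s consumes no reference; skipped", rec.query_name)
            continue
        cursor = rec.pos  # 1-based next reference base
        for op, length in rec.cigar:
            if op in adding:
                lo = max(cursor, region.start) - region.start
                hi = min(cursor + length, region.end) - region.start
                if hi > lo:
                    diff[lo] += 1
                    diff[hi] -= 1
                cursor += length
            elif op in "DN":
                cursor += length
            # I, S, H, P consume no reference
    return CoverageVector(region, np.cumsum(diff[:n]), dataset_id)


def extract_junctions(records: Iterable[AlignmentRecord]) -> list[SpliceJunction]:
    """Splice junctions from CIGAR N ops, merged and support-counted.

    An N op of length L whose skip begins after reference position q yields
    the intron (q+1, q+L); identical introns across reads are merged with
    summed support.  Sorted by (chrom, intron_start, intron_end).
    """
    counts: dict[tuple[str, int, int], int] = {}
    for rec in records:
        if not rec.is_mapped:
            continue
        cursor = rec.pos
        for op, length in rec.cigar:
            if op == "N":
                key = (rec.chrom, cursor, cursor + length - 1)
                counts[key] = counts.get(key, 0) + 1
                cursor += length
            elif op in "M=XD":
                cursor += length
    return [
        SpliceJunction(chrom, start, end, support)
        for (chrom, start, end), support in sorted(counts.items())
    ]


def write_depth_txt(cov: CoverageVector, sink: IO[str]) -> None:
    """Write per-position depth as ``chrom<TAB>pos<TAB>depth`` lines.

    One line per region position, ascending, 1-based — byte-deterministic
    for a fixed input.
    """
    chrom = cov.region.chrom
    start = cov.region.start
    sink.writelines(
        f"{chrom}\t{start + i}\t{int(d)}\n" for i, d in enumerate(cov.depth)
    )


def read_depth_txt(source: IO[str], dataset_id: str = "") -> CoverageVector:
    """Parse a depth TXT (as written by :func:`write_depth_txt`)."""
    chrom = None
    positions: list[int] = []
    depths: list[int] = []
    for lineno, line in enumerate(source, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            c, p, d = line.split("\t")
        except ValueError as exc:
            raise ValueError(f"depth TXT line {lineno}: expected 3 columns") from exc
        if chrom is None:
            chrom = c
        elif c != chrom:
            raise ValueError(f"depth TXT line {lineno}: mixed chromosomes")
        positions.append(int(p))
        depths.append(int(d))
    if chrom is None:
        raise ValueError("empty depth TXT")
    if positions != list(range(positions[0], positions[0] + len(positions))):
        raise ValueError("depth TXT positions not contiguous ascending")
    region = GenomicRegion(chrom, positions[0], positions[0] + len(positions))
    return CoverageVector(region, np.array(depths, dtype=np.int64), dataset_id)


def write_junctions_bed(junctions: Iterable[SpliceJunction], sink: IO[str]) -> None:
    """Junctions as BED: 0-based half-open intron interval, score = support."""
    for i, j in enumerate(junctions):
        sink.write(
            f"{j.chrom}\t{j.intron_start - 1}\t{j.intron_end}\tJUNC{i + 1}\t{j.support}\n"
        )
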