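"""SAM alignment records, parsing, and the quality / region-pair filters.

The filters reproduce a targeted mining protocol for a weakly expressed
locus: reads are kept when their mean base quality clears a Phred threshold
(Q20 by default) and when the read pair maps into a fixed genomic window —
by default a pair survives when EITHER mate touches the window, which
maximises sensitivity for sparse signal.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from pancmine.regions import GenomicRegion

log = logging.getLogger(__name__)

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
#: CIGAR ops that consume the reference
REF_CONSUMING = frozenset("MDN=X")
#: CIGAR ops that consume the query sequence
QUERY_CONSUMING = frozenset("MIS=X")
#: ops that place an aligned query base on the reference
ALIGNED_OPS = frozenset("M=X")


class SamFormatError(ValueError):
    """Raised for a malformed SAM line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass
class AlignmentRecord:
    """One SAM alignment line (mandatory columns only; tags ignored)."""

    query_name: str
    flag: int
    chrom: str
    pos: int  # 1-based leftmost mapped position; 0 when unmapped
    mapq: int
    cigar: list[tuple[str, int]]
    mate_chrom: str | None = None
    mate_pos: int | None = None
    tlen: int = 0
    seq: str | None = None
    base_qualities: list[int] | None = None

    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_mapped(self) -> bool:
        return not self.flag & FLAG_UNMAPPED

    @property
    def is_primary(self) -> bool:
        return not self.flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY)

    @property
    def reference_span(self) -> int:
        """Number of reference bases consumed by the CIGAR."""
        return sum(n for op, n in self.cigar if op in REF_CONSUMING)

    @property
    def reference_end(self) -> int:
        """1-based end-exclusive reference end (pos + consumed span)."""
        return self.pos + self.reference_span

    def mean_base_quality(self) -> float | None:
        if not self.base_qualities:
            return None
        return sum(self.base_qualities) / len(self.base_qualities)

    def to_sam_line(self) -> str:
        cigar = (
            "".join(f"{n}{op}" for op, n in self.cigar) if self.cigar else "*"
        )
        rnext = "*"
        if self.mate_chrom is not None:
            rnext = "=" if self.mate_chrom == self.chrom else self.mate_chrom
        qual = (
            "".join(chr(q + 33) for q in self.base_qualities)
            if self.base_qualities
            else "*"
        )
        return "\t".join(
            [
                self.query_name,
                str(self.flag),
                self.chrom if self.chrom else "*",
                str(self.pos),
                str(self.mapq),
                cigar,
                rnext,
                str(self.mate_pos or 0),
                str(self.tlen),
                self.seq or "*",
                qual,
            ]
        )


def parse_cigar(text: str) -> list[tuple[str, int]]:
    """Parse a CIGAR string into (op, length) tuples; '*' gives []."""
    if text == "*":
        return []
    ops = _CIGAR_RE.findall(text)
    if "".join(f"{n}{op}" for n, op in ops) != text:
        raise ValueError(f"unparsable CIGAR {text!r}")
    parsed = [(op, int(n)) for n, op in ops]
    if any(n <= 0 for _, n in parsed):
        raise ValueError(f"CIGAR with non-positive length: {text!r}")
    return parsed


def read_sam(stream: IO[str] | Iterable[str]) -> Iterator[AlignmentRecord]:
    """Yield one AlignmentRecord per alignment line of a SAM text stream.

    Header lines (starting ``@``) are skipped.  Malformed lines raise
    :class:`SamFormatError` naming the offending 1-based line number.
    """
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("@"):
            continue
        fields = line.split("\t")
        if len(fields) < 11:
            raise SamFormatError(
                f"expected >= 11 tab-separated columns, got {len(fields)}", lineno
            )
        (qname, flag_s, rname, pos_s, mapq_s, cigar_s,
         rnext, pnext_s, tlen_s, seq, qual) = fields[:11]
        try:
            flag = int(flag_s)
            pos = int(pos_s)
            mapq = int(mapq_s)
            pnext = int(pnext_s)
            tlen = int(tlen_s)
            cigar = parse_cigar(cigar_s)
        except ValueError as exc:
            raise SamFormatError(str(exc), lineno) from exc
        seq_val = None if seq == "*" else seq
        if seq_val is not None and cigar:
            qlen = sum(n for op, n in cigar if op in QUERY_CONSUMING)
            if qlen != len(seq_val):
                raise SamFormatError(
                    f"CIGAR query length {qlen} != sequence length {len(seq_val)}",
                    lineno,
                )
        quals = None if qual == "*" else [ord(c) - 33 for c in qual]
        mate_chrom: str | None
        if rnext == "*":
            mate_chrom = None
        elif rnext == "=":
            mate_chrom = rname
        else:
            mate_chrom = rnext
        yield AlignmentRecord(
            query_name=qname,
            flag=flag,
            chrom="" if rname == "*" else rname,
            pos=pos,
            mapq=mapq,
            cigar=cigar,
            mate_chrom=mate_chrom,
            mate_pos=pnext if pnext > 0 else None,
            tlen=tlen,
            seq=seq_val,
            base_qualities=quals,
        )


def write_sam(
    records: Iterable[AlignmentRecord],
    sink: IO[str],
    header_lines: Sequence[str] = (),
) -> None:
    """Write records as SAM text, preceded by the given header lines."""
    for h in header_lines:
        sink.write(h.rstrip("\n") + "\n")
    for rec in records:
        sink.write(rec.to_sam_line() + "\n")


def filter_quality(
    records: Iterable[AlignmentRecord], min_q: float = 20
) -> Iterator[AlignmentRecord]:
    """Keep mapped, primary records whose mean base quality >= ``min_q``.

    Records lacking base qualities fall back to ``mapq >= min_q``.  The
    threshold is inclusive, matching common read-trimming convention for a
    "Q20" cut.
    """
    if min_q < 0:
        raise ValueError(f"min_q must be non-negative, got {min_q}")
    for rec in records:
        if not rec.is_mapped or not rec.is_primary:
            continue
        mq = rec.mean_base_quality()
        score = mq if mq is not None else rec.mapq
        if score >= min_q:
            yield rec


def filter_region_pairs(
    records: Iterable[AlignmentRecord],
    region: GenomicRegion,
    require_both_mates: bool = False,
) -> list[AlignmentRecord]:
    """Keep records belonging to pairs that map into ``region``.

    Default policy: a paired record is kept when its own reference span
    overlaps the window OR its mate's start falls inside it — so both mates
    of a kept pair are retained even if one maps far away.  Single-end
    records are kept on own-span overlap only.  With
    ``require_both_mates=True`` a paired record needs its own overlap AND
    its mate's start in-window.
    """
    kept = []
    any_on_chrom = False
    for rec in records:
        if not rec.is_mapped:
            continue
        if rec.chrom == region.chrom:
            any_on_chrom = True
        own = region.overlaps(rec.chrom, rec.pos, rec.reference_end)
        mate = (
            rec.is_paired
            and rec.mate_chrom == region.chrom
            and rec.mate_pos is not None
            and region.contains(rec.mate_pos)
        )
        if rec.is_paired:
            keep = (own and mate) if require_both_mates else (own or mate)
        else:
            keep = own
        if keep:
            kept.append(rec)
    if not any_on_chrom:
        log.warning("no records on %s; region filter returns empty set", region.chrom)
    return kept


@dataclass
class ManifestEntry:
    dataset_id: str
    path: Path
    group_label: str = ""


@dataclass
class DatasetManifest:
    """The inventory of datasets contributing to a composite signal."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.dataset_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate dataset_ids in manifest: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def by_group(self, label: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.group_label == label]


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a TSV manifest with columns dataset_id, path, group_label."""
    path = Path(path)
    entries = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"dataset_id", "path"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"manifest {path} must have columns dataset_id, path "
                f"(optionally group_label); got {reader.fieldnames}"
            )
        for row in reader:
            p = Path(row["path"])
            if not p.is_absolute():
                p = path.parent / p
            entries.append(
                ManifestEntry(row["dataset_id"], p, row.get("group_label", "") or "")
            )
    return DatasetManifest(entries)
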