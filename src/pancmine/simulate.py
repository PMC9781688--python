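"""Synthetic read simulator for composite-detection experiments.

The simulator embeds a short, weakly expressed, optionally spliced,
non-polyadenylated transcript in a larger background sequence and emits
aligned reads dataset by dataset.  Its default geometry mirrors the
MUC5B-promoter pancRNA study system scaled onto a 20 kb synthetic genome:
an 18.5 kb analysis window whose last two kilobases contain a 1712 nt
transcript with an internal 860 nt intron, the tag SNP falling on the
second nucleotide of exon 2.

Per-dataset read counts model the mining regime the toolkit exists for:
transcript fragment numbers are Poisson with a small mean and are thinned
by a capture probability when the transcript is not polyadenylated (polyA
selection losing most fragments), so a single dataset usually contributes
zero to a handful of reads — below any per-dataset caller — while the sum
over many datasets is detectable.  Reads are error-free by default (a
substitution-rate flag exists); base-calling noise is orthogonal to the
aggregation mechanism under test.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from pancmine.alignment_io import AlignmentRecord
from pancmine.aggregate import call_segments, collapse, ExpressedSegment
from pancmine.coverage import SpliceJunction, compute_depth, extract_junctions
from pancmine.regions import GenomicRegion, span_length

_BASES = np.array(list("ACGT"))

#: Default synthetic geometry (all 1-based, end-exclusive).
GENOME_LEN = 20_000
CHROM = "synth1"
DEFAULT_WINDOW = GenomicRegion(CHROM, 1_000, 19_500)  # 18,500 bp
DEFAULT_TRANSCRIPT = GenomicRegion(CHROM, 17_530, 19_242)  # 1712 nt
DEFAULT_INTRON = GenomicRegion(CHROM, 18_130, 18_990)  # 860 nt; exon1 = 600 nt
DEFAULT_SNP_OFFSET = 1_461  # 0-based within transcript: second base of exon 2


@dataclass
class SimulatedLocus:
    """A synthetic genome carrying one embedded transcript."""

    genome_seq: str
    chrom: str
    transcript: GenomicRegion
    intron: GenomicRegion | None
    snp_offset: int  # 0-based offset within the transcript
    is_polyadenylated: bool = False
    window: GenomicRegion = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if self.transcript.end - 1 > len(self.genome_seq):
            raise ValueError("transcript extends past genome end")
        if self.intron is not None:
            t, i = self.transcript, self.intron
            if not (t.start < i.start and i.end < t.end):
                raise ValueError("intron must lie strictly inside the transcript")
        if not 0 <= self.snp_offset < span_length(self.transcript):
            raise ValueError("snp_offset outside transcript span")

    @property
    def exon_regions(self) -> list[GenomicRegion]:
        t = self.transcript
        if self.intron is None:
            return [t]
        return [
            GenomicRegion(t.chrom, t.start, self.intron.start),
            GenomicRegion(t.chrom, self.intron.end, t.end),
        ]

    @property
    def spliced_length(self) -> int:
        return sum(span_length(e) for e in self.exon_regions)

    @property
    def snp_pos(self) -> int:
        """Genomic 1-based position of the tag SNP."""
        return self.transcript.start + self.snp_offset


def default_locus(seed: int = 0, is_polyadenylated: bool = False) -> SimulatedLocus:
    """The standard 20 kb fixture with a 1712 nt spliced transcript."""
    rng = np.random.default_rng(seed)
    genome = "".join(rng.choice(_BASES, size=GENOME_LEN))
    return SimulatedLocus(
        genome_seq=genome,
        chrom=CHROM,
        transcript=DEFAULT_TRANSCRIPT,
        intron=DEFAULT_INTRON,
        snp_offset=DEFAULT_SNP_OFFSET,
        is_polyadenylated=is_polyadenylated,
    )


@dataclass
class DatasetProfile:
    """Read-generation parameters for one simulated dataset.

    Defaults describe a single polyA-selected library seen through a
    targeted window: an expected 8 transcript fragments of which ~25%
    survive library prep (the transcript is non-polyadenylated), so a
    typical dataset contributes about two transcript reads, plus a few
    stray background reads scattered over the genome.
    """

    dataset_id: str = "sim"
    n_background_reads: int = 3
    transcript_fragments: float = 8.0
    capture_prob: float = 0.25
    read_len: int = 75
    paired: bool = False
    fragment_len: int = 200
    spliced_fraction: float = 0.2
    substitution_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("capture_prob", "spliced_fraction", "substitution_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.n_background_reads < 0 or self.transcript_fragments < 0:
            raise ValueError("counts must be >= 0")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")


def _transcript_to_genome(
    locus: SimulatedLocus, start: int, length: int, spliced: bool
) -> tuple[int, list[tuple[str, int]], str]:
    """Map a [start, start+length) slice of the (spliced) transcript to
    (genomic pos, CIGAR, sequence)."""
    t = locus.transcript
    g = locus.genome_seq
    if not spliced or locus.intron is None:
        pos = t.start + start
        return pos, [("M", length)], g[pos - 1 : pos - 1 + length]
    e1_len = locus.intron.start - t.start
    intron_len = span_length(locus.intron)
    end = start + length
    if end <= e1_len:  # entirely in exon 1
        pos = t.start + start
        return pos, [("M", length)], g[pos - 1 : pos - 1 + length]
    if start >= e1_len:  # entirely in exon 2
        pos = locus.intron.end + (start - e1_len)
        return pos, [("M", length)], g[pos - 1 : pos - 1 + length]
    a = e1_len - start  # bases in exon 1
    b = length - a
    pos = t.start + start
    seq = (
        g[pos - 1 : pos - 1 + a]
        + g[locus.intron.end - 1 : locus.intron.end - 1 + b]
    )
    return pos, [("M", a), ("N", intron_len), ("M", b)], seq


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hit):
        chars[i] = rng.choice(_BASES[_BASES != chars[i]])
    return "".join(chars)


def _make_record(
    name: str,
    chrom: str,
    pos: int,
    cigar: list[tuple[str, int]],
    seq: str,
    flag: int = 0,
    mate_chrom: str | None = None,
    mate_pos: int | None = None,
    tlen: int = 0,
) -> AlignmentRecord:
    return AlignmentRecord(
        query_name=name,
        flag=flag,
        chrom=chrom,
        pos=pos,
        mapq=60,
        cigar=cigar,
        mate_chrom=mate_chrom,
        mate_pos=mate_pos,
        tlen=tlen,
        seq=seq,
        base_qualities=[40] * len(seq),
    )


def _emit(
    locus: SimulatedLocus,
    prof: DatasetProfile,
    rng: np.random.Generator,
    name: str,
    frag_start: int,
    frag_len: int,
    spliced: bool,
    on_transcript: bool,
) -> list[AlignmentRecord]:
    """One read (or read pair) from a fragment in transcript or genome space."""

    def build(offset: int) -> tuple[int, list[tuple[str, int]], str]:
        if on_transcript:
            return _transcript_to_genome(locus, offset, prof.read_len, spliced)
        pos = offset + 1  # genome space, 0-based offset in
        return pos, [("M", prof.read_len)], locus.genome_seq[offset : offset + prof.read_len]

    if not prof.paired:
        pos, cigar, seq = build(frag_start)
        flag = 16 if rng.random() < 0.5 else 0
        return [_make_record(name, locus.chrom, pos, cigar,
                             _mutate(seq, prof.substitution_rate, rng), flag)]
    r1_off = frag_start
    r2_off = frag_start + frag_len - prof.read_len
    p1, c1, s1 = build(r1_off)
    p2, c2, s2 = build(r2_off)
    span = (p2 + sum(n for op, n in c2 if op in "MDN=X")) - p1
    rec1 = _make_record(name, locus.chrom, p1, c1,
                        _mutate(s1, prof.substitution_rate, rng),
                        flag=0x1 | 0x2 | 0x20 | 0x40,
                        mate_chrom=locus.chrom, mate_pos=p2, tlen=span)
    rec2 = _make_record(name, locus.chrom, p2, c2,
                        _mutate(s2, prof.substitution_rate, rng),
                        flag=0x1 | 0x2 | 0x10 | 0x80,
                        mate_chrom=locus.chrom, mate_pos=p1, tlen=-span)
    return [rec1, rec2]


def simulate_dataset(
    locus: SimulatedLocus,
    prof: DatasetProfile,
    rng: np.random.Generator | None = None,
) -> list[AlignmentRecord]:
    """Simulate one dataset's aligned reads over the synthetic locus.

    Transcript fragment count is Poisson(``transcript_fragments``), thinned
    binomially by ``capture_prob`` when the transcript is not
    polyadenylated.  Spliced fragments (probability ``spliced_fraction``)
    are drawn on the spliced transcript and acquire M-N-M CIGARs when they
    cross the junction; unspliced fragments are uniform over the full
    genomic span.  Background reads start uniformly over the genome.
    Deterministic for a fixed seed; records are returned coordinate-sorted.
    """
    if rng is None:
        rng = np.random.default_rng(prof.seed)
    min_exon = min(span_length(e) for e in locus.exon_regions)
    if prof.read_len > min_exon:
        raise ValueError(
            f"read_len {prof.read_len} exceeds shortest exon ({min_exon} nt)"
        )
    frag_span = prof.fragment_len if prof.paired else prof.read_len
    records: list[AlignmentRecord] = []

    k = rng.poisson(prof.transcript_fragments)
    if not locus.is_polyadenylated and k > 0:
        k = rng.binomial(k, prof.capture_prob)
    for i in range(k):
        spliced = locus.intron is not None and rng.random() < prof.spliced_fraction
        tlen_space = locus.spliced_length if spliced else span_length(locus.transcript)
        flen = min(frag_span, tlen_space)
        start = int(rng.integers(0, tlen_space - flen + 1))
        records.extend(
            _emit(locus, prof, rng, f"{prof.dataset_id}_t{i + 1}", start, flen,
                  spliced, on_transcript=True)
        )

    glen = len(locus.genome_seq)
    for i in range(prof.n_background_reads):
        flen = min(frag_span, glen)
        start = int(rng.integers(0, glen - flen + 1))
        records.extend(
            _emit(locus, prof, rng, f"{prof.dataset_id}_b{i + 1}", start, flen,
                  spliced=False, on_transcript=False)
        )

    records.sort(key=lambda r: (r.chrom, r.pos, r.query_name, r.flag))
    return records


def sam_header(locus: SimulatedLocus, prof: DatasetProfile | None = None) -> list[str]:
    lines = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{locus.chrom}\tLN:{len(locus.genome_seq)}",
    ]
    if prof is not None:
        lines.append(f"@CO\tdataset={prof.dataset_id}\tseed={prof.seed}")
    return lines


def _detected(
    locus: SimulatedLocus,
    vectors,
    caller_params: dict,
) -> tuple[bool, list[ExpressedSegment]]:
    sig = collapse(vectors)
    segs = call_segments(sig, **caller_params)
    t = locus.transcript
    hit = any(s.overlaps(t) for s in segs)
    return hit, segs


def power_experiment(
    locus: SimulatedLocus,
    prof_template: DatasetProfile,
    n_datasets_grid: Sequence[int],
    reps: int = 50,
    caller_params: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Detection probability of the embedded transcript vs number of datasets.

    For each n in the grid and each replicate: simulate n datasets, collapse
    their window depth, call segments, and score detection as any called
    segment overlapping the transcript.  Fully reproducible from ``seed``.
    """
    if len(n_datasets_grid) == 0:
        raise ValueError("empty n_datasets grid")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    caller_params = caller_params or {}
    root = np.random.SeedSequence(seed)
    rows = []
    for n, child in zip(n_datasets_grid, root.spawn(len(n_datasets_grid))):
        rep_seeds = child.spawn(reps)
        detected = 0
        for rep_ss in rep_seeds:
            if n == 0:
                continue
            rng = np.random.default_rng(rep_ss)
            vectors = []
            for d in range(n):
                prof = dataclasses.replace(prof_template, dataset_id=f"ds{d + 1}")
                recs = simulate_dataset(locus, prof, rng=rng)
                vectors.append(compute_depth(recs, locus.window, prof.dataset_id))
            hit, _ = _detected(locus, vectors, caller_params)
            detected += hit
        rows.append(
            {
                "n_datasets": n,
                "detected": detected,
                "reps": reps,
                "detection_probability": detected / reps,
            }
        )
    return pd.DataFrame(rows)


def junction_recovery_check(
    locus: SimulatedLocus,
    prof: DatasetProfile,
    rng: np.random.Generator | None = None,
) -> tuple[bool, list[SpliceJunction]]:
    """Would the pipeline see the embedded intron if splicing were present?

    Simulates one dataset and extracts junctions; returns whether the exact
    (first, last skipped base) coordinates of the locus intron were
    recovered, together with all recovered junctions.
    """
    records = simulate_dataset(locus, prof, rng=rng)
    junctions = extract_junctions(records)
    if locus.intron is None:
        return False, junctions
    expected = (locus.chrom, locus.intron.start, locus.intron.end - 1)
    recovered = any(
        (j.chrom, j.intron_start, j.intron_end) == expected for j in junctions
    )
    return recovered, junctions
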