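"""Collapsing per-dataset coverage into a composite signal.

The central operation is an unnormalized elementwise sum of per-dataset
depth vectors over a shared window: transcripts whose per-dataset read
counts sit at background-noise level become visible only in the sum over
many independent datasets.  A segment caller then turns the composite
profile into discrete "expressed" intervals, and a group comparison table
supports contrasts such as differentiated epithelium vs basal cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
import pandas as pd

from pancmine.coverage import CoverageVector
from pancmine.regions import GenomicRegion, span_length


@dataclass
class CompositeSignal:
    """Collapsed multi-dataset depth with provenance."""

    region: GenomicRegion
    total_depth: np.ndarray
    per_dataset_nonzero: np.ndarray
    dataset_ids: list[str]

    def __post_init__(self) -> None:
        self.total_depth = np.asarray(self.total_depth, dtype=np.int64)
        self.per_dataset_nonzero = np.asarray(self.per_dataset_nonzero, dtype=np.int64)
        n = span_length(self.region)
        if self.total_depth.shape != (n,) or self.per_dataset_nonzero.shape != (n,):
            raise ValueError("array lengths must equal region span")
        if (self.total_depth < self.per_dataset_nonzero).any():
            raise ValueError("total_depth < per_dataset_nonzero somewhere")

    @property
    def n_datasets(self) -> int:
        return len(self.dataset_ids)


@dataclass(frozen=True)
class ExpressedSegment:
    """A called run of covered positions (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    max_depth: int
    mean_depth: float
    breadth: float  # fraction of segment positions at/above the calling threshold

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("segment end < start")
        if not 0.0 <= self.breadth <= 1.0:
            raise ValueError("breadth outside [0,1]")

    def overlaps(self, region: GenomicRegion) -> bool:
        return region.overlaps(self.chrom, self.start, self.end + 1)


def collapse(
    vectors: Sequence[CoverageVector], scale_per_million: bool = False
) -> CompositeSignal:
    """Elementwise sum of per-dataset depth vectors over a shared region.

    Order-independent.  With ``scale_per_million`` each dataset is first
    scaled to depth per million summed in-window bases (then rounded back to
    integers) to compensate for heterogeneous library sizes; the default is
    the raw, unnormalized sum.
    """
    if not vectors:
        raise ValueError("collapse requires at least one CoverageVector")
    region = vectors[0].region
    bad = [v.dataset_id or f"<vector {i}>" for i, v in enumerate(vectors)
           if v.region != region]
    if bad:
        raise ValueError(f"region mismatch for datasets: {bad}")
    n = span_length(region)
    total = np.zeros(n, dtype=np.float64 if scale_per_million else np.int64)
    nonzero = np.zeros(n, dtype=np.int64)
    for v in vectors:
        d = v.depth
        if scale_per_million:
            s = d.sum()
            total += d * (1e6 / s) if s > 0 else 0.0
        else:
            total += d
        nonzero += d > 0
    if scale_per_million:
        total = np.rint(total).astype(np.int64)
    return CompositeSignal(region, total, nonzero, [v.dataset_id for v in vectors])


def call_segments(
    sig: CompositeSignal,
    min_depth: int = 2,
    min_len: int = 50,
    max_gap: int = 10,
) -> list[ExpressedSegment]:
    """Maximal runs of positions with total depth >= ``min_depth``.

    Sub-threshold gaps of at most ``max_gap`` positions between runs are
    bridged; bridged runs shorter than ``min_len`` are discarded.  Segment
    boundaries always fall on above-threshold positions.  Returned sorted
    and non-overlapping.
    """
    if min_depth < 1 or min_len < 1 or max_gap < 0:
        raise ValueError("require min_depth >= 1, min_len >= 1, max_gap >= 0")
    above = sig.total_depth >= min_depth
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    # split where consecutive above-threshold positions are > max_gap+1 apart
    breaks = np.flatnonzero(np.diff(idx) > max_gap + 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    segments = []
    for s, e in zip(starts, ends):
        lo, hi = idx[s], idx[e]  # 0-based inclusive
        if hi - lo + 1 < min_len:
            continue
        window = sig.total_depth[lo : hi + 1]
        segments.append(
            ExpressedSegment(
                chrom=sig.region.chrom,
                start=sig.region.start + int(lo),
                end=sig.region.start + int(hi),
                max_depth=int(window.max()),
                mean_depth=float(window.mean()),
                breadth=float((window >= min_depth).mean()),
            )
        )
    return segments


def compare_groups(
    a: CompositeSignal,
    b: CompositeSignal,
    labels: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Per-position comparison of two composite signals on the same region.

    Normalized columns are depth per million summed in-window depth; the
    ``difference`` column is the normalized difference (a − b).
    """
    if a.region != b.region:
        raise ValueError(f"region mismatch: {a.region} vs {b.region}")
    la, lb = labels
    sum_a, sum_b = a.total_depth.sum(), b.total_depth.sum()
    norm_a = a.total_depth * (1e6 / sum_a) if sum_a > 0 else np.zeros_like(a.total_depth, dtype=float)
    norm_b = b.total_depth * (1e6 / sum_b) if sum_b > 0 else np.zeros_like(b.total_depth, dtype=float)
    return pd.DataFrame(
        {
            "chrom": a.region.chrom,
            "pos": np.arange(a.region.start, a.region.end),
            f"depth_{la}": a.total_depth,
            f"depth_{lb}": b.total_depth,
            f"norm_{la}": norm_a,
            f"norm_{lb}": norm_b,
            "difference": norm_a - norm_b,
        }
    )


def write_bedgraph(sig: CompositeSignal, sink: IO[str], name: str = "composite") -> None:
    """Composite depth as bedGraph (0-based half-open, run-length merged)."""
    sink.write(f'track type=bedGraph name="{name}"\n')
    depth = sig.total_depth
    if len(depth) == 0:
        return
    change = np.flatnonzero(np.diff(depth)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(depth)]))
    base = sig.region.start - 1  # 0-based
    for s, e in zip(starts, ends):
        sink.write(f"{sig.region.chrom}\t{base + s}\t{base + e}\t{int(depth[s])}\n")


def write_segments_bed(segments: Sequence[ExpressedSegment], sink: IO[str]) -> None:
    for i, seg in enumerate(segments):
        sink.write(
            f"{seg.chrom}\t{seg.start - 1}\t{seg.end}\tSEG{i + 1}\t{seg.max_depth}\n"
        )
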