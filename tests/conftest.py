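import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pancmine.alignment_io import AlignmentRecord
from pancmine.regions import GenomicRegion

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_record(rng, chrom="chr11", lo=100, hi=400, name="r") -> AlignmentRecord:
    """A random mapped single-end record with a mixed M/I/D/N/S CIGAR."""
    n_ops = rng.integers(1, 5)
    cigar = []
    prev = None
    for _ in range(n_ops):
        choices = [op for op in "MIDNS" if op != prev]
        op = str(rng.choice(choices))
        length = int(rng.integers(1, 30 if op != "N" else 120))
        cigar.append((op, length))
        prev = op
    # ensure at least one aligned op so the record consumes reference
    if not any(op in "M=X" for op, _ in cigar):
        cigar.insert(0, ("M", int(rng.integers(1, 30))))
    qlen = sum(n for op, n in cigar if op in "MIS=X")
    seq = "".join(rng.choice(list("ACGT"), size=qlen))
    quals = [int(q) for q in rng.integers(2, 41, size=qlen)]
    return AlignmentRecord(
        query_name=f"{name}{rng.integers(1_000_000)}",
        flag=0,
        chrom=chrom,
        pos=int(rng.integers(lo, hi)),
        mapq=int(rng.integers(0, 61)),
        cigar=cigar,
        seq=seq,
        base_qualities=quals,
    )


def brute_force_depth(records, region: GenomicRegion) -> np.ndarray:
    """Independent per-(record, position) counting oracle for depth."""
    depth = np.zeros(len(region), dtype=np.int64)
    for rec in records:
        if not rec.is_mapped or rec.chrom != region.chrom:
            continue
        ref = rec.pos
        for op, length in rec.cigar:
            if op in "M=X":
                for p in range(ref, ref + length):
                    if region.contains(p):
                        depth[p - region.start] += 1
                ref += length
            elif op in "DN":
                ref += length
    return depth
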