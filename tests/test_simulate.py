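import dataclasses
import io

import numpy as np
import pytest

from pancmine.alignment_io import read_sam, write_sam
from pancmine.coverage import compute_depth
from pancmine.regions import span_length
from pancmine.simulate import (
    DatasetProfile,
    default_locus,
    junction_recovery_check,
    power_experiment,
    sam_header,
    simulate_dataset,
)


@pytest.fixture(scope="module")
def locus():
    return default_locus(0)


def _sam_bytes(locus, prof):
    records = simulate_dataset(locus, prof)
    buf = io.StringIO()
    write_sam(records, buf, sam_header(locus, prof))
    return buf.getvalue()


class TestSimulateDataset:
    def test_default_geometry_mirrors_study_locus(self, locus):
        assert span_length(locus.transcript) == 1712
        assert locus.intron is not None and span_length(locus.intron) == 860
        # tag SNP on the second base of exon 2
        assert locus.snp_pos == locus.intron.end + 1
        assert len(locus.genome_seq) == 20_000

    def test_no_fragments_only_background(self, locus):
        prof = DatasetProfile(transcript_fragments=0, n_background_reads=5, seed=1)
        records = simulate_dataset(locus, prof)
        assert len(records) == 5
        assert all(r.query_name.split("_")[-1].startswith("b") for r in records)

    def test_zero_capture_of_nonpolyadenylated_transcript(self, locus):
        prof = DatasetProfile(
            transcript_fragments=50, capture_prob=0.0, n_background_reads=0, seed=1
        )
        assert simulate_dataset(locus, prof) == []

    def test_polyadenylated_transcript_skips_thinning(self, locus):
        poly = dataclasses.replace(locus, is_polyadenylated=True)
        prof = DatasetProfile(
            transcript_fragments=50, capture_prob=0.0, n_background_reads=0, seed=1
        )
        assert len(simulate_dataset(poly, prof)) > 0

    def test_same_seed_gives_byte_identical_sam(self, locus):
        prof = DatasetProfile(dataset_id="d1", seed=99)
        assert _sam_bytes(locus, prof) == _sam_bytes(locus, prof)

    def test_different_seeds_differ(self, locus):
        a = _sam_bytes(locus, DatasetProfile(dataset_id="d1", seed=1))
        b = _sam_bytes(locus, DatasetProfile(dataset_id="d1", seed=2))
        assert a != b

    def test_round_trips_through_read_sam_losslessly(self, locus):
        prof = DatasetProfile(
            dataset_id="d1", seed=7, transcript_fragments=30, capture_prob=1.0
        )
        records = simulate_dataset(locus, prof)
        buf = io.StringIO()
        write_sam(records, buf, sam_header(locus, prof))
        back = list(read_sam(io.StringIO(buf.getvalue())))
        assert [r.to_sam_line() for r in back] == [r.to_sam_line() for r in records]

    def test_read_sequences_match_genome(self, locus):
        prof = DatasetProfile(
            dataset_id="d1", seed=3, transcript_fragments=20, capture_prob=1.0,
            spliced_fraction=0.0,
        )
        for rec in simulate_dataset(locus, prof):
            start = rec.pos - 1
            assert rec.seq == locus.genome_seq[start : start + len(rec.seq)]

    def test_spliced_reads_carry_intron_length_n_op(self, locus):
        prof = DatasetProfile(
            dataset_id="d1", seed=5, transcript_fragments=200, capture_prob=1.0,
            spliced_fraction=1.0,
        )
        records = simulate_dataset(locus, prof)
        spliced = [r for r in records if any(op == "N" for op, _ in r.cigar)]
        assert spliced, "expected junction-spanning reads"
        for rec in spliced:
            (n_len,) = [n for op, n in rec.cigar if op == "N"]
            assert n_len == span_length(locus.intron)

    def test_paired_mode_emits_consistent_mates(self, locus):
        prof = DatasetProfile(
            dataset_id="d1", seed=11, paired=True, transcript_fragments=10,
            capture_prob=1.0, n_background_reads=4,
        )
        records = simulate_dataset(locus, prof)
        by_name = {}
        for r in records:
            by_name.setdefault(r.query_name, []).append(r)
        for name, pair in by_name.items():
            assert len(pair) == 2, name
            r1, r2 = sorted(pair, key=lambda r: r.flag)
            assert r1.mate_pos == r2.pos and r2.mate_pos == r1.pos
            assert r1.is_paired and r2.is_paired

    def test_read_longer_than_exon_rejected(self, locus):
        prof = DatasetProfile(read_len=300, seed=1)  # exon 2 is 252 nt
        with pytest.raises(ValueError, match="exon"):
            simulate_dataset(locus, prof)

    def test_substitution_rate_perturbs_reads(self, locus):
        base = DatasetProfile(dataset_id="d", seed=13, transcript_fragments=50,
                              capture_prob=1.0)
        noisy = dataclasses.replace(base, substitution_rate=0.2)
        clean_recs = simulate_dataset(locus, base)
        noisy_recs = simulate_dataset(locus, noisy)
        mismatches = sum(
            a != b for rec in noisy_recs
            for a, b in zip(rec.seq, locus.genome_seq[rec.pos - 1 :])
            if not any(op == "N" for op, _ in rec.cigar)
        )
        assert mismatches > 0
        assert all(r.seq for r in clean_recs)


class TestPowerExperiment:
    def test_grid_zero_gives_zero_probability(self, locus):
        tab = power_experiment(locus, DatasetProfile(), [0], reps=3, seed=1)
        assert tab.detection_probability.tolist() == [0.0]

    def test_empty_grid_rejected(self, locus):
        with pytest.raises(ValueError):
            power_experiment(locus, DatasetProfile(), [], reps=3)

    def test_saturation_at_high_expression(self, locus):
        prof = DatasetProfile(transcript_fragments=1000)
        tab = power_experiment(locus, prof, [1], reps=10, seed=5)
        assert tab.detection_probability.iloc[0] == 1.0

    def test_reproducible_for_fixed_seed(self, locus):
        prof = DatasetProfile()
        a = power_experiment(locus, prof, [1, 5], reps=10, seed=3)
        b = power_experiment(locus, prof, [1, 5], reps=10, seed=3)
        assert a.equals(b)

    def test_monotone_in_expression_level(self, locus):
        weak = DatasetProfile(transcript_fragments=1.0)
        strong = DatasetProfile(transcript_fragments=100.0)
        p_weak = power_experiment(locus, weak, [3], reps=20, seed=9)
        p_strong = power_experiment(locus, strong, [3], reps=20, seed=9)
        assert (
            p_strong.detection_probability.iloc[0]
            >= p_weak.detection_probability.iloc[0]
        )

    def test_composite_mean_depth_matches_expectation(self, locus):
        """Law-of-large-numbers parameter recovery over the transcript span.

        Expected per-dataset transcript coverage is
        transcript_fragments * capture_prob * read_len bases, plus the
        background's share; the composite mean over the transcript span
        should converge to n times that density.
        """
        prof = DatasetProfile()
        n, reps = 5, 60
        root = np.random.SeedSequence(2026)
        t = locus.transcript
        means = []
        for ss in root.spawn(reps):
            rng = np.random.default_rng(ss)
            depths = []
            for d in range(n):
                recs = simulate_dataset(
                    locus, dataclasses.replace(prof, dataset_id=f"d{d}"), rng=rng
                )
                depths.append(compute_depth(recs, t).depth)
            means.append(np.sum(depths, axis=0).mean())
        per_dataset = (
            prof.transcript_fragments * prof.capture_prob * prof.read_len
            / span_length(t)
            + prof.n_background_reads * prof.read_len / len(locus.genome_seq)
        )
        expected = n * per_dataset
        assert np.mean(means) == pytest.approx(expected, rel=0.15)


class TestJunctionRecovery:
    def test_embedded_intron_recovered_exactly(self, locus):
        prof = DatasetProfile(
            spliced_fraction=0.5, transcript_fragments=500, capture_prob=1.0, seed=21
        )
        recovered, junctions = junction_recovery_check(locus, prof)
        assert recovered
        coords = {(j.intron_start, j.intron_end) for j in junctions}
        assert (locus.intron.start, locus.intron.end - 1) in coords

    def test_no_splicing_no_junctions(self, locus):
        prof = DatasetProfile(spliced_fraction=0.0, transcript_fragments=100,
                              capture_prob=1.0, seed=22)
        recovered, junctions = junction_recovery_check(locus, prof)
        assert not recovered and junctions == []

    def test_all_recovered_introns_have_locus_intron_length(self, locus):
        prof = DatasetProfile(
            spliced_fraction=1.0, transcript_fragments=300, capture_prob=1.0, seed=23
        )
        _, junctions = junction_recovery_check(locus, prof)
        assert junctions
        for j in junctions:
            assert j.intron_length == span_length(locus.intron)
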