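# Methods

## Composite coverage mining

The core procedure takes a manifest of independently produced alignment
files (SAM), a genomic window, and produces a composite per-base depth
signal:

1. **Quality filter.** A record survives when it is mapped, primary, and
   its mean base quality is ≥ `min_q` (default 20, inclusive). "Q20" is
   interpreted as mean base quality in line with common read-trimming
   convention; records without stored base qualities fall back to
   MAPQ ≥ `min_q`. Secondary and supplementary alignments are discarded
   before depth so no read is counted twice.
2. **Region pair filter.** A paired record is kept when its own reference
   span overlaps the window **or** its mate's start falls inside it
   (either-mate policy, both mates retained). This is the
   sensitivity-maximising reading for a sparse signal, where the window
   boundary would otherwise orphan half of an informative pair;
   `--both-mates` switches to the strict policy. Single-end records are
   kept on own-span overlap only.
3. **Depth.** CIGAR ops M/=/X add one unit of depth per covered position;
   D and N consume reference without adding depth (a `count_deletions`
   flag exists); I/S/H/P add nothing. Depth is int64 throughout so sums
   over arbitrarily many datasets cannot overflow. Overlapping mates
   double-count by default — the composite is a raw pileup, not a
   fragment count.
4. **Collapse.** The composite is the **unnormalized** elementwise sum of
   per-dataset depth vectors over the shared window, together with a
   per-position count of contributing datasets. An optional per-million
   scaling (`--normalize`) compensates for heterogeneous library sizes;
   it is off by default because the raw sum is the quantity of interest
   when individual libraries contribute 0–3 reads.
5. **Segment calling.** Expressed segments are maximal runs of positions
   with composite depth ≥ `min_depth` (default 2), bridging sub-threshold
   gaps ≤ `max_gap` (default 10 nt) and discarding runs shorter than
   `min_len` (default 50 nt). These are operational defaults for a decision
   layer that published analyses typically make by eye; all three are
   exposed as flags, and segment boundaries always fall on above-threshold
   positions.

Splice junctions are read directly off N CIGAR ops: an N of length L whose
skip begins after reference position q is the intron (q+1, q+L); identical
introns are merged with summed support.

Coordinates are 1-based with end-exclusive spans (`span = end − start`);
internal arrays are 0-based half-open. Depth TXT, bedGraph and BED writers
convert at the boundary.

## Conservation and motifs

Window identity is computed per alignment column window (default 50
columns, step 1): identity = identical unambiguous-nucleotide columns /
window, with gap or N columns counting as mismatches (the conservative,
VISTA-like choice). Windows at or above the threshold (default 0.70,
**inclusive** — 35/50 qualifies, 34/50 does not) are merged in column space
and reported over the reference row's ungapped coordinates with the merged
span's column-level mean identity. The bundled motif set contains only the
two SMAD binding elements whose sequences are established — the canonical
CAGAC box and the 5GC SBE GGC(GC)(CG), expanded to the words GGCGC and
GGCCG; the FOXA2 site near the locus has no published consensus we would
bundle, so motif patterns are user-suppliable IUPAC strings, scanned on
both strands with minus-strand hits reported in plus-strand coordinates.

## qPCR quantification

Replicate Ct values are summarised by the arithmetic mean; spread is the
sample standard deviation (labelled sd — reports that print "±" without
naming sd vs sem are treated as sd). ΔCt = mean(target) − mean(reference),
sd propagating in quadrature; fold difference between conditions is
2^(−ΔΔCt). A Ct at or beyond the protocol's 40 cycles, or an explicit
"ND", is an undetected reaction: it propagates as a flag and an undefined
(NaN) ΔCt, never an imputed number. Amplification efficiency is
(10^(−1/m) − 1) × 100 from the least-squares slope m of Ct vs log10
relative input, so a perfect doubling per cycle (m = −3.3219) scores 100%;
the statistic is invariant to uniform Ct offsets.

## The simulator and what it does (not) show

`simulate.default_locus` builds a 20 kb uniform-random genome carrying the
study geometry scaled in: an 18,500 nt analysis window
(synth1:1,000–19,500), a 1712 nt transcript at synth1:17,530–19,242 with a
600 nt exon 1, an 860 nt intron and a 252 nt exon 2, and the tag SNP on the
second nucleotide of exon 2 — the same window/transcript proportions and
splice geometry as the MUC5B-promoter locus.

Per dataset, the transcript contributes K ~ Poisson(`transcript_fragments`,
default 8) fragments, thinned binomially by `capture_prob` (default 0.25)
when the transcript is not polyadenylated — modelling polyA selection
losing most fragments, so a typical library carries about two transcript
reads. A fraction `spliced_fraction` (default 0.2) of fragments is drawn on
the spliced transcript and acquires an M-N-M CIGAR when it crosses the
junction; the rest are uniform over the unspliced span. Background is
`n_background_reads` (default 3) uniform 75 nt reads over the whole genome
— the simplest falsifiable stand-in for the near-empty "dark region" the
mining targets. Reads are error-free by default (`substitution_rate` flag);
base-calling noise is orthogonal to the aggregation mechanism under test.
One master seed drives everything; per-replicate and per-dataset streams
are derived by `SeedSequence` splitting, so every SAM is byte-reproducible.

These defaults were fixed once so that a single dataset yields a
transcript-overlapping segment in well under 20% of replicates while
twenty collapsed datasets detect it essentially always — the regime the
method exists for. The default power experiment (50 replicates per point,
grid 1–20 datasets) runs in under a second.

What the simulator does **not** emulate: realistic fragment-length and
coverage-bias models, sequencing error profiles, multi-mapping and
alignment artefacts, batch structure across datasets, or single-cell
chemistry. Passing power tests therefore demonstrate the aggregation
arithmetic and the caller's behaviour under the stated sampling model, not
performance on any particular public dataset.

## Numerical and degenerate-input choices

* Depth computation uses a difference-array + cumulative sum; identical to
  naive per-position counting (tested against it) but O(reads + span).
* An alignment shorter than the identity window yields a single truncated
  window and a logged warning rather than an error.
* `collapse([])` is an error; a region mismatch error names the offending
  dataset ids.
* Records whose CIGAR consumes zero reference are skipped with a warning.
* Ct ≤ 0 is rejected; empty replicate groups are errors, not NaNs.
* The CLI removes partial per-dataset outputs when a later dataset fails,
  and every run writes a JSON parameter echo sufficient to reproduce it.
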