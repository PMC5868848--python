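# Methods

## The problem this package models

Modified DNA immunoprecipitation (MoDIP) uses an antibody against
8-hydroxy-2'-deoxyguanosine (8OHdG) to pull down oxidised genomic fragments,
analogous to MeDIP for methylated DNA. After sequencing, the analysis question
is: *which genomic regions are recurrently oxidised?* Answering it requires
(i) mapping short reads, (ii) recognising reads too repetitive to place,
(iii) subtracting the background that a no-antibody control recovers, and
(iv) merging the surviving mapped reads into candidate oxidation regions.
modipkit implements that workflow at desk scale on a synthetic reference with
full truth tracking, so every stage can be validated before real data arrive.

## The synthetic world

The generator's defaults are the stated validation dataset, not free
parameters: 100 reads of 25 bp; both 200-bp source regions tiled with reads
overlapping 5 bp (starts step by 20 bp, 9 reads per region, 18 tiled reads),
the regions separated by exactly 100 bp; the remaining 82 reads dispersed
uniformly over all chromosomes outside the tiled regions; 75 reads modified
(round-robin: single-base substitution, 5-nt insertion at floor(len/2), 5-nt
deletion centered at floor(len/2)); 25 negative-control background sequences,
each an exact copy of a mock read or a reference extract overlapping one by
more than half the read length.

Two dataset statements cannot both hold ("half the sequences" tiled vs. two
200-bp regions at 20-bp steps, which yield 18 reads); the default honors the
region geometry and fills to 100 with dispersed reads, and `n_tiled` lets a
user force any tiled count instead.

The reference is 3 chromosomes x 10 kb of i.i.d. uniform bases (named chr1,
chr2, chrX) with
planted structure recorded as truth: three repeat classes (SINE-like 150 bp,
LINE-like 400 bp, microsatellite-like 60 bp of a tandem 3-mer motif), three
copies each; one exactly duplicated 200-bp locus pair; the two tiled regions.
Plantings never overlap one another or the tiled block, so tiled reads map
uniquely. What this world does **not** emulate: real base composition and GC
content, divergent (non-identical) repeat copies, sequencing error profiles,
quality scores, and coverage depth biases. A green test therefore establishes
algorithmic correctness of each stage, not performance on a real genome —
percentages measured on human-genome runs with external aligners cannot be
reproduced here by construction and are replaced by exact property checks (perfect
mapping of verbatim unique-region reads, DP-oracle agreement for indel reads,
planted repeat-fraction recovery within 5 points).

## Mapping

**Ungapped regime.** Candidate loci are diagonals implied by exact k-mer seed
hits at every read offset (k = 5 by default, both strands; reverse-strand
placements query the reverse complement against the forward index). Each
candidate is scored by Hamming mismatches over the full read; a candidate is
discarded if it has more than 1 mismatch in the read's *first 5 bases* (for a
reverse-strand placement these sit at the 3' end of the forward window) or
more than 2 mismatches in total. With best-mode, the minimum-mismatch
candidate wins; two or more equally good loci give `multi` (deliberately, in
place of an arbitrary choice); none gives `unaligned`. With the default caps
(total <= 2, k = 5, 25-bp reads) every valid locus retains an exact 5-mer
(pigeonhole: the longest exact run is at least ceil(23/3) = 8 bases), so the
seed search is complete and the mapper is exactly equivalent to an exhaustive
scan — which the test suite asserts on 500 random reads.

**Gapped regime.** Used to rescue reads the ungapped regime leaves unaligned
(the escalation order of the pipeline) or standalone. Seed hits vote per
(strand, chromosome, diagonal); diagonals within `band` (default 8 bp, chosen
> the 5-nt injected indels) merge into one candidate window of
`read_len + 2*band` reference bases. When more than 20 windows arise, windows
are kept by descending vote count (votes >= 2 preferred): an indel read's
flanks contribute many exact seeds to the true diagonals, while random
diagonals almost always get a single vote, so the pruning does not lose the
true locus for the read geometry this package generates. Each window is
aligned by a fitting Gotoh dynamic program — read global, window local (free
window end gaps), affine gaps with match +2, mismatch -3, gap open -6, gap
extend -1 (first gap base pays the open penalty) — with full traceback for
the placement, gap and mismatch counts. The window margin is the band; at
window sizes of ~41 bases a cell-level band would save nothing. An alignment
is accepted when its score reaches 0.6 x 2 x read_len (unmodified read: 50;
one substitution: 45; one 5-nt deletion: 30 vs. threshold 24; one 5-nt
insertion: 40 vs. 36 — all accepted, random placements rejected). Ties across
distinct loci give `multi`. An insertion can create a motif matching another
locus exactly; the gapped aligner then prefers that locus — the mis-mapping
mechanism expected in real data, reproduced in a dedicated test.

**Accuracy.** A unique alignment is correct when chromosome and start match
truth — exactly for substitution/pristine reads, within ±5 bp for indel reads
because an indel legitimately shifts the optimal start. Per-base depth is
accumulated over unique alignments only.

## Repeat screen

A deliberate stand-in for library-based masking (RepeatMasker/Repbase are out
of scope): the library is the set of planted element sequences, and matching
is exact substring matching with `min_match` = 11 bases, both orientations.
Masking every matching 11-mer window reproduces maximal-substring masking
exactly, because any match of length L >= 11 is the union of its 11-mer
windows. Overlapping matches are unioned. A read is *repeat-dominated* when
strictly more than 20 of its bases are masked (the threshold is read as a
strict inequality); such reads are too generic to map uniquely. With no
divergence model, this screen recovers planted composition exactly but would
under-mask diverged real repeats.

## Background subtraction

Rules in order, first match recorded as the reason: (1) *identical* — same
sequence and same interval as a background entry; (2) *contained* — read
interval entirely within a background interval (equal bounds count as
contained); (3) *overlap* — shared bases divided by the **read's own length**
strictly greater than the threshold (default 0.5). The denominator choice is
the package's: a bare "more than 50% overlap" rule does not fix a
denominator, and the query-length one is the natural reading of a per-read
filter; the
threshold is exposed as an option for users who want a different convention.
A 25-bp read sharing 12 bases (48%) is kept; 13 bases (52%) is removed; the
50% point itself is kept.

## Clustering

Reads are bucketed per chromosome and each chromosome is processed
independently (the streaming contract: no stage holds more than one
chromosome's sorted reads beyond the initial bucketing), stably sorted by
(start, end). A left-to-right scan merges a read into the open cluster when
`read.start - cluster.end <= gap` in half-open coordinates — so gap = 0
merges overlapping *and* abutting reads ("0 bp between" two reads means
abutting); a `require_overlap` flag gives the strict-overlap alternative.
Supported gap range is 0–50 bp. The scan is exactly equivalent to connected
components of the distance-<=-gap interval graph, asserted against a
brute-force closure oracle on 1,000 random instances. Outputs are two BED5
files (membership with comma-joined read ids; counts with the member count in
the score column) and a region x sample count table whose rows are the merged
union of all samples' cluster intervals — each sample's column sums to its
surviving read count, making the table directly usable by count-based
differential tools; the differential statistics themselves are out of scope.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere internally and in all BED
  output; reports can render 1-based inclusive on request; no external
  coordinate convention is assumed.
- Strand is recorded on alignments but ignored by denoising and clustering.
- Accuracy with zero unique alignments reports 0.0 with `n_unique` = 0 rather
  than NaN.
- Empty read sets: composition summarisation refuses (no denominator); an
  empty background keeps everything; an empty cluster list writes two empty
  files.
- Mapping ties are broken toward `multi`, never an arbitrary locus; all
  candidate enumeration is sorted so runs are bit-reproducible.
- All randomness flows from one integer seed through `numpy` generators;
  identical configuration + seed gives byte-identical artifact directories.

## Known limitations

Exact-match masking and alignment caps tuned to 25-bp reads do not transfer
to real, diverged genomes; the seed-vote pruning in the gapped mapper is
heuristic beyond the generated read geometry; paired-end reads, quality
scores, and BAM are unsupported (SAM subset and the tab dialect only); the
pipeline is single-sample per run, with multi-sample aggregation only at the
count-table step.
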