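# Methods

## Panel model

A locus is an amplicon reference sequence, the repeating motif of its
SSR, and 0-based half-open coordinates of the repeat array on that
reference. Motifs must be primitive (not themselves a tandem repetition
of a shorter unit, checked via the doubling trick: `u` is non-primitive
iff it occurs inside `(u+u)[1:-1]`), 2–10 bp, over A/C/G/T. The
reference slice at the array coordinates must consist of exact tandem
motif copies, and at least 20 bases of flank must exist on each side;
the 20 bp flank anchors used during typing are always derived from the
reference, never stored separately, so they cannot drift out of sync.

## Read assignment and orientation

Each read is compared against every locus reference in both
orientations. Candidates are screened with a bit-parallel edit-distance
computation (edlib, infix mode, shorter sequence as query); the
minimum-distance candidates are then aligned semi-globally with affine
gap scoring: match +2, mismatch −2, gap of length L costs 4 + L. End
gaps on both sequences are free, so the shorter sequence aligns
end-to-end inside the longer one and unaligned read tails become soft
clips. Affine gap opening matters here: under plain edit distance a
multi-base insertion can be split across equal-cost placements
(observed as `2I 1= 2I` for a 4-base repeat-unit insertion), which
corrupts the boundary projection described below; with an opening
penalty the contiguous placement is uniquely optimal.

A read is assigned to the best-scoring locus iff its score reaches
`min_score_frac × 2 × min(len(read), len(ref))` — the stated fraction of
the perfect score attainable over the aligned core. The min-length scale
(rather than read length) keeps the threshold meaningful for reads that
carry non-amplicon tails: a 200 bp read whose amplicon core is 115 bp
can never reach 60 % of `2 × 200` however perfect the core match is.
Random 200-mers score below 0.18 on this scale against the simulated
panels, so assignment is robust across the whole `min_score_frac` range
0.5–0.8. An exact score tie between two loci leaves the read unassigned
as ambiguous. Minus-strand reads are reverse-complemented (qualities
reversed) before typing. Pre-aligned reads can be ingested from SAM,
trusting RNAME/FLAG/CIGAR and resolving `M` ops into `=`/`X` against the
panel reference.

## Repeat counting

**Precise.** Both 20 bp flank anchors are placed in the read by
fewest-mismatch ungapped search (ties broken leftmost, at most 2
mismatches per anchor; the right anchor is searched only right of the
left one). The repeat number is the longest run of consecutive exact
motif copies in the region between the anchors, starting at any offset.
Any substitution or indel inside the array truncates the run; a flank
indel loses the anchor and the read.

**Broad.** The reference array coordinates are projected onto the read
through the alignment CIGAR: insertions inside the region extend it,
insertions immediately at a boundary are attributed to the array,
deletions shrink it, and a boundary falling inside a deletion snaps to
the deletion's read position. Flank errors therefore cannot move the
boundaries. The projected region is scanned unit by unit: a window of
motif length with Hamming distance ≤ 1 counts as one unit and is always
consumed; at most 4 substitutions are tolerated per region. Only where
a window fails may the scan resynchronize by 1 to motif length − 1
bases in either direction, consuming the skipped stretch as one
indel-carrying unit (at most 2 such events). Three restrictions keep
the count honest, each motivated by a concrete overcount: the scan must
open on an in-tolerance window (otherwise junk preceding the array
counts as a free unit); resynchronization is only attempted at failing
windows (otherwise a self-similar array such as six AGAGA copies with
one SNP is reinterpreted as seven shorter units); and the skipped
stretch must equal the motif with one contiguous indel applied
(otherwise a lone foreign base passes as a "unit with two bases
deleted"). The maximum over all admissible start offsets is reported.
The scan is memoized on (position, substitutions used, indels used),
keeping it linear-ish in region length in practice.

**Naive.** As a foil, the precise counter applied to the whole read with
no boundaries. A flank SNP that creates a motif copy makes it overcount,
which is exactly the error boundary determination prevents.

Reads whose region yields zero units are reported `untypeable`, never as
a zero-repeat allele.

## Genotype calling and QC

Typed reads are tallied per locus by repeat count. The top typing alone
(fraction ≥ 0.8) is a homozygote; the top two (each ≥ 0.2) a
heterozygote. Tables with fewer than 30 typed reads are not called
(depth). Satellite typings one repeat unit away from a called allele
with fewer reads are flagged as probable stutter but never subtracted
or promoted. A locus is flagged low quality when more than two typings
each hold ≥ 0.2 of reads, when even the top typing holds < 0.3, or when
the broad and precise counters disagree on > 0.5 of its reads. Alleles
are named both ways in the outputs: length-style `SSR{count×motiflen}`
and star-style `{MOTIF}*{count}`.

## Simulator

Simulated reads are `Random_L + Flank_L(35 bp) + SSR + Flank_R(35 bp) +
Random_R` with total length uniform in [180, 220], half of each class
reverse-complemented, read ids `BMSTC_<class digit>_<ordinal>`. The
five-class pool (7000 reads) exercises each pipeline stage: A — 2000
clean reads with one SNP per flank; B — 1000 reads of a heterozygous
locus (alleles differing by one full repeat unit, split evenly); C —
2000 reads of a heterozygous locus whose second allele is a
SNP-interrupted six-copy array; D — 1000 fully random reads; E — 1000
class-A reads at the lowest base quality (Phred 2 vs 40). The expected
fates — E filtered, D unassigned, everything else typed — are part of
the ground truth and verified exactly.

The per-variant benchmark generates 10 000 reads per locus over three
loci with motif lengths 3/4/5 (ATC×8, AGAT×7, AGAGA×6), in four modes:
no variant, one SNP at the array centre, one SNP at the left-flank
centre, and a 2 bp deletion at the left-flank centre. None of the
variants changes the true repeat number. Broad typing reaches 100 % in
all twelve (mode, locus) cells; precise typing fails exactly the
SSR-internal-SNP and flank-deletion modes — the two classical failure
modes of exact-run, exact-flank genotypers.

Synthetic locus flanks force the base abutting the array to differ from
the adjacent motif base, so a repeat-length change cannot slide into the
flank under equally optimal alignments; real assay panels choose flanks
with the same property in mind.

Evaluation metrics: `Er`, the fraction of expected-typeable reads not
typed to their true (locus, repeat count); `Et`, the fraction of
distinct true (locus, allele) pairs not recovered by the genotype calls.
Filtered and random classes are excluded from both denominators.

## Numerical and engineering choices

* All randomness flows through `numpy.random.default_rng` seeded
  explicitly; same seed, same bytes, including FASTQ output.
* Anchor search and CIGAR `=`/`X` run construction are vectorized with
  numpy (`sliding_window_view` and flat-nonzero on byte arrays).
* Alignment uses established libraries (edlib for screening,
  Biopython's PairwiseAligner for the scored CIGAR) rather than a
  hand-rolled dynamic program; the fault-tolerant counter is hand-rolled
  because its unit-wise semantics, not alignment, is the method.
* Typical problem sizes: panels of 3–10 loci, amplicons ≲ 300 bp, reads
  ≈ 200 bp, pools of 10⁴–10⁵ reads. One read costs ~0.5 ms end to end;
  the 7000-read pool runs in ~4 s and the 120 000-read benchmark in
  ~2 min on one core.

## Limitations

* Single-sample, diploid calling only; no population-level binning of
  alleles across samples.
* The quality filter is per-read; no trimming or per-base masking.
* Somatic mosaicism, triallelic patterns and severe stutter are flagged
  as low quality rather than modeled.
* The simulator draws flank/padding errors but not platform-specific
  error profiles (homopolymer bias, quality decay along the read).
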