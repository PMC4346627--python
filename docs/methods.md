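# Methods

## Scope and model

`mirtail` quantifies two things from single-end small-RNA libraries:
per-mature-miRNA expression (raw tag counts and CPM) and the
composition of +1-nt 3′ extensions, split into genome-templated
extensions and non-templated additions (NTA) of A, C, G or U. The
comparison statistic is the between-condition change in
mono-uridylation, in percentage points. The pipeline assumes:

* single-end reads carrying a known 3′ adapter, inserts 18–26 nt;
* ungapped alignment (substitutions only, no indels) with all
  qualifying placements reported;
* a mature-miRNA annotation whose coordinates are consistent with the
  alignment reference, since the genome base immediately 3′ of the
  mature end decides which +1 nucleotide is templated;
* no modelling of precursor hairpins, Dicer processing, ligation bias
  or UMIs.

Internally every coordinate is 0-based half-open; GFF3 (1-based
closed) is converted at the parser boundary only. On the minus strand
the mature "5′ start" is the larger genomic coordinate, and all offsets
are measured in transcript orientation, which keeps the assignment rule
strand-symmetric (a property the test suite checks by mirroring the
genome).

## Stage-by-stage choices

**Trimming.** The adapter is located by scanning for the leftmost
position where a prefix of the adapter matches with at least
`min_overlap` (default 6) aligned bases and a mismatch fraction of at
most `max_mismatch_rate` (default 0.1); everything from that position
on is cut. This is a deliberate simplification of seed-scoring
trimmers: on clean data the behaviour is identical, on marginal hits it
may cut where a log-odds scorer would not. Reads shorter than
`min_length` (default 18) are discarded. The library size *N* is the
number of reads kept after trimming and the length filter, before
mapping — a choice recorded in the run manifest, since CPM values
depend on it. Reads longer than 26 nt stay in the library (and in *N*)
but are excluded later by the assignment length rule.

**Alignment.** The built-in `toy_align` is an exhaustive
shift-and-accumulate scan over every contig, strand and start
position; it is exact by construction and intended for desk-scale
references (tens of kilobases), where it doubles as its own
sensitivity guarantee. At full scale an external all-alignments
aligner writing NM/MD tags can be ingested instead (`read_sam`);
indel-containing records are rejected with a count, and alignment
quality-sum rules belong to the external aligner, not this package.
Base-quality strings are carried but not modelled (the simulator emits
constant maximum quality).

**Minimum-mismatch retention.** Per read, alignments at the read's
minimum mismatch count are kept and all others dropped; identical
placements are collapsed (logged). This best-stratum rule, not a
unique-mapping filter, is what downstream counting consumes.

**Assignment and counting.** The ±3 nt window on the 5′ start is
closed; tags of length outside [18, 26] are never assigned. A read
whose retained alignments reach several mature names contributes total
weight 1 split equally (fractional counting); `weighting="unique"`
drops such reads instead. Both modes are exposed because multi-mapper
policy is a genuine free parameter in small-RNA quantification; the
fractional default avoids double-counting while keeping paralog
families quantifiable. Matures annotated at several loci under one
name are collapsed by name before counting. CPM uses the trimming
stage's *N*, never the count-table column sum. CPM ratios with a zero
denominator are reported as undefined, not infinity. rRNA decoy
alignments win the retention filter for rRNA-derived reads and, lying
outside the miRNA annotation, produce no assignments; decoy reads
still count in *N*.

**Tail classification.** Classification is restricted to
canonical-start tags (5′ offset 0) by default: the defining rule —
body identical to the genome reference, one extra 3′ base — leaves no
room for 5′ offsets. A +1 base equal to the genome base at the
position following the mature 3′ end is a templated extension, never
an NTA; consequently the genome-templated nucleotide has no NTA class
at that locus (it is unobservable), and the percentage denominator is
the mature count plus the three observable NTA counts. With a genome
+1 base of A this reduces to the canonical form U% = t·100/(m+t+c+g).
Tails of ≥2 nt, shortened tags, and tags with internal mismatches are
class `other` and excluded from the formula. For a locus whose +1 base
is T, mono-uridylation is unobservable and the profile reports NaN —
such miRNAs are excluded from ranking rather than silently scored 0.
An alternative statistic, u·100/m (uridylated per exactly-matching
mature), is emitted alongside as `mono_u_pct_vs_mature`; the
mature-plus-tails denominator is primary throughout.

**Ranking.** The change statistic is the percentage-point difference
(mut − wt); a relative change is emitted for transparency. miRNAs are
analysed when both conditions have at least `min_tags` (default 10)
denominator tags; ranking is ascending by delta (most decreased =
rank 1) with deterministic tie-breaks (greater total tags, then name),
and the top quartile of decreased uridylation is ranks ≤ ⌈n/4⌉ with no
interpolation. The `min_tags` inclusion threshold and tie policy are
explicit configuration because no principled universal value exists;
they are always recorded in output.

## The synthetic generator

The generator embeds 20–23 nt mature sequences directly in a random
genome (alternating strands, padded and separated so assignment
windows cannot collide), records the +1 genome base per locus, and
draws reads per miRNA and condition as: Poisson tag count around the
configured mean; 5′ offset from a distribution concentrated at 0
(restricted per-read to offsets keeping the tag inside 18–26 nt);
a +1 tail category from {none, templated, A, C, G, U}; the full
adapter appended. A drawn nucleotide equal to the genome +1 base is
physically indistinguishable from a templated extension and is
recorded as templated, so truth labels always satisfy the NTA
definition. Default tail composition (none 0.70, templated 0.05,
A 0.12, C 0.015, G 0.015, U 0.10) makes A and U dominate, as in
mammalian small-RNA libraries.

Sequencing error is modelled per read: with probability `error_rate`
(default 0.001) a single substitution at a uniform insert position.
This deliberately simple error model keeps the mapping between error
events and classification flips one-to-one; it does not emulate
per-base, position-dependent or quality-correlated Illumina error
profiles, homopolymer artefacts, ligation bias or true multi-nt
tails — so passing recovery tests demonstrate correctness of the
formulas and bookkeeping, not robustness to every real-data pathology.
Randomness derives from per-miRNA streams spawned from the master
seed, so adding miRNAs leaves existing ones byte-identical.

`simulate_tailing_counts` exposes the same model's count-level
marginal (Poisson totals thinned by the offset-0 probability ×
multinomial tail classes, with the templated-base fold-in) for
replicate studies of the ranking statistic where materialising reads
adds nothing.

## Problem sizes and numerical notes

Desk-scale defaults were chosen to make sampling noise small relative
to the effects studied: oracle checks use 200 reads of 18–26 nt
against a 10 kb genome at ≤2 mismatches; classifier-recovery runs use
20 miRNAs at ~2,500 reads each; the planted mono-uridylation drop
(0.10 → 0.06) is measured end-to-end at ~2,500 reads per miRNA per
condition, and its rank-1 recovery across 100 count-level replicates
at a mean of 5,000 tags per miRNA per condition — deep coverage, under
which the planted miRNA's expected −4.0-point change stands ~4 standard
errors clear of its 19 competitors' sampling noise. In the planted
studies the tail composition sets C- and G-tail probabilities to zero
so that, at a locus whose +1 base is C or G, the expected uridylation
percentage equals the U-tail probability exactly and the planted drop
is exactly −4.0 points.

Percentages on an empty denominator are NaN and flagged, never 0.
Poisson draws make realized library sizes random; all interval checks
in the tests use exact scipy binomial/Poisson quantiles at the realized
sample sizes. All TSV outputs are deterministic given the seed; the
run manifest (package version, parameters, input SHA-256 checksums,
per-stage record counts) suffices to reproduce a run bit-identically.

## Known limitations

* The toy aligner is exhaustive, not indexed: quadratic in genome ×
  reads, unsuitable beyond desk scale; full-scale use expects an
  external aligner's SAM/BAM.
* Only +1-nt tails are analysed; multi-nt tails are counted as
  `other`, 3′-trimmed isomiRs and internal editing are out of scope.
* Uridylation at loci whose +1 genome base is T is structurally
  unobservable under the classification rule; such miRNAs are excluded
  from ranking.
* The trimmer diverges from seed-scoring trimmers on marginal,
  high-mismatch adapter hits.
* Fractional multi-mapper weighting is a modelling choice, not an
  estimate of true origin; families of near-identical matures remain
  jointly, not individually, quantified.
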