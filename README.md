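# mirtail

Small RNA-seq analysis of mature microRNA expression and 3′ tailing:
a tested, reusable pipeline that quantifies per-miRNA tag counts (CPM)
and +1-nt 3′ non-templated additions (NTA), with a focus on
**mono-uridylation** — a single non-templated U appended to the miRNA
3′ end, a modification associated with miRNA destabilisation. The
package is aimed at anyone comparing isomiR tailing between two
conditions (e.g. wild-type versus mutant T cells) from single-end
small-RNA libraries.

A synthetic-data module generates toy genomes, miRBase-style
annotations (GFF3) and two-condition read sets with a complete truth
table, so every stage of the pipeline is verifiable end to end without
any external downloads.

## The method

Starting from adapter-bearing single-end reads:

1. **Trim** — remove the 3′ sequencing adapter
   (`TCGTATGCCGTCTTCTGCTTGT` by default) and discard reads shorter
   than 18 nt. The number of kept reads is the library size *N*.
2. **Align** — report *all* ungapped placements of each read with at
   most *k* substitutions (built-in exhaustive toy aligner, or ingest
   SAM/BAM from an external all-alignments aligner). Optional rRNA
   decoy contigs capture ribosomal reads.
3. **Minimum-mismatch retention** — per read, keep exactly the
   alignments at that read's minimum mismatch count.
4. **Assign** — an 18–26 nt tag is assigned to a mature miRNA when its
   strand-aware 5′ start lies within ±3 nt of the annotated mature 5′
   start. Raw counts *n* are normalised as CPM = *n* × 10⁶ / *N*.
5. **Classify +1 tails** — a canonical-start tag that is exactly the
   mature sequence is class *m*; a tag one nt longer whose body matches
   the mature sequence is a **templated extension** if its last base
   equals the genome base following the mature 3′ end, otherwise a
   non-templated addition of A, C, G or U. With a genome +1 base of A,
   the non-templated-U percentage is

   ​  U% = *t* × 100 / (*m* + *t* + *c* + *g*),

   i.e. each observable NTA is taken relative to the sum of mature tags
   and all observable non-templated tails; the nucleotide matching the
   genome +1 base is unobservable as an NTA and templated extensions
   never enter the formula.
6. **Compare conditions** — per miRNA, the change in mono-uridylation
   in percentage points (mutant − wild type); miRNAs with enough tags
   in both conditions are ranked (most decreased first) and the top
   quartile of decreased uridylation (⌈*n*/4⌉ ranks) is called, then
   intersected with CPM fold changes to flag miRNAs that both lose
   uridylation and accumulate.

## Worked example

Simulate a 10-miRNA two-condition study in which one miRNA
(`mir-sim-004`) has its U-tail probability dropped from 0.10 (wt) to
0.01 (mut), then run every stage:

```python
import pandas as pd
from mirtail.pipeline import RunConfig, run_all

cfg = RunConfig(
    outdir="example_run", seed=7, min_tags=50,
    simulate={
        "n_mirnas": 10, "genome_length": 8000, "mean_abundance": 1200,
        "tail_overrides": {
            "mir-sim-004": {"mut": {"none": 0.79, "templated": 0.05, "A": 0.12,
                                    "C": 0.015, "G": 0.015, "U": 0.01}}
        },
    },
)
manifest = run_all(cfg)
ranked = pd.read_csv("example_run/uridylation_change.tsv", sep="\t")
```

The ranked table recovers the planted drop at rank 1:

```
 mirna_name    pct_wt   pct_mut  delta_points  rank  in_top_quartile_decrease
mir-sim-004 12.082262  1.136364    -10.945899     1                      True
mir-sim-008 12.895377 10.731707     -2.163670     2                      True
mir-sim-007 13.009198 11.621967     -1.387232     3                      True
mir-sim-005 12.289157 11.346633     -0.942523     4                     False
mir-sim-006 11.842105 11.670762     -0.171344     5                     False
```

`pct_wt`/`pct_mut` are per-condition mono-uridylation percentages
(U-tailed tags per mature-plus-observable-NTA tags, ×100);
`delta_points` is their difference, and the top quartile of 10 analysed
miRNAs is the first ⌈10/4⌉ = 3 ranks. Unplanted miRNAs sit near the
simulated baseline (~12%, i.e. 0.10 U-tail probability over a 0.83
denominator mass) while the planted miRNA drops by ~11 points. The run
directory also holds per-condition `counts_*.tsv` (n, N, CPM),
`tailing_*.tsv` (m/A/C/G/U/templated counts and percentages),
`plus_one_composition.tsv` (per-nucleotide NTA distributions) and a
`manifest.json` with parameters, input checksums and per-stage record
counts; the same stages are available as `mirtail simulate | trim |
filter-alignments | count | nta | diff | run` on the command line.

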