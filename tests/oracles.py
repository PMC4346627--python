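"""Independent oracles used by the unit and acceptance suites.

These deliberately avoid the library's own code paths: the alignment
oracle is a per-position python scan, and the retention oracle is a
pandas group-by-then-min recomputation.
"""
import pandas as pd

from mirtail.core import Genome, Read, revcomp


def naive_scan(read: Read, genome: Genome, max_mm: int) -> set:
    """Exhaustive position-by-position alignment scan over both strands."""
    hits = set()
    for name, contig in genome.contigs.items():
        for strand, query in (("+", read.sequence), ("-", revcomp(read.sequence))):
            for s in range(len(contig) - len(query) + 1):
                mm = 0
                for a, b in zip(query, contig[s:s + len(query)]):
                    if a != b:
                        mm += 1
                        if mm > max_mm:
                            break
                if mm <= max_mm:
                    hits.add((name, strand, s, mm))
    return hits


def groupby_min_retention(alignments) -> set:
    """Expected retained set: per read, placements at minimal mismatches."""
    df = pd.DataFrame(
        [(a.read_id, a.reference, a.strand, a.start, a.mismatches) for a in alignments],
        columns=["read_id", "reference", "strand", "start", "mm"],
    ).drop_duplicates()
    df["kmin"] = df.groupby("read_id")["mm"].transform("min")
    best = df[df["mm"] == df["kmin"]]
    return set(map(tuple, best[["read_id", "reference", "strand", "start"]].values))
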