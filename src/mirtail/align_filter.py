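"""Multi-hit alignment ingest and minimum-mismatch retention.

The toy aligner reports, exhaustively, every ungapped placement of a
read on either strand with at most ``max_mismatches`` substitutions —
a desk-scale stand-in for an all-alignments aligner run. The retention
filter then keeps, per read, exactly the alignments at that read's
minimum mismatch count (the best stratum), which is the custom
post-processing step the whole quantification rests on.
"""
from __future__ import annotations

import logging
import re
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .core import Alignment, Genome, Read, revcomp

logger = logging.getLogger(__name__)

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


# ----------------------------------------------------------------- toy align

def _contig_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _mismatch_profile(contig: np.ndarray, read: str) -> np.ndarray:
    """Mismatch count of the read against every start position of the
    contig (vectorised shift-and-accumulate)."""
    L = len(read)
    n = len(contig) - L + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int32)
    counts = np.zeros(n, dtype=np.int32)
    rbytes = read.encode()
    for j in range(L):
        counts += contig[j:j + n] != rbytes[j]
    return counts


def toy_align(
    reads: Iterable[Read], genome: Genome, max_mismatches: int = 3
) -> list[Alignment]:
    """Exhaustive ungapped alignment of each read to both strands of
    every contig, reporting all placements with <= max_mismatches
    substitutions."""
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    arrays = {name: _contig_array(seq) for name, seq in genome.contigs.items()}
    out: list[Alignment] = []
    for read in reads:
        for name, arr in arrays.items():
            for strand, query in (("+", read.sequence), ("-", revcomp(read.sequence))):
                profile = _mismatch_profile(arr, query)
                for pos in np.nonzero(profile <= max_mismatches)[0]:
                    out.append(
                        Alignment(
                            read_id=read.read_id, reference=name, strand=strand,
                            start=int(pos), sequence=read.sequence,
                            mismatches=int(profile[pos]),
                        )
                    )
    return out


# ------------------------------------------------------------------- SAM in

class UngappedRecordError(ValueError):
    """Record contains indels; the pipeline's alignment mode is ungapped."""


def count_mismatches(record: pysam.AlignedSegment) -> int:
    """Mismatch count of a SAM record from its NM tag, falling back to
    the MD tag; indel-containing records are rejected."""
    if record.cigartuples and any(op in (1, 2, 3) for op, _ in record.cigartuples):
        raise UngappedRecordError(f"{record.query_name}: indel in CIGAR")
    if record.has_tag("NM"):
        return int(record.get_tag("NM"))
    if record.has_tag("MD"):
        md = record.get_tag("MD")
        mm = 0
        for num, deletion, sub in _MD_TOKEN.findall(md):
            if sub:
                mm += 1
            elif deletion:
                raise UngappedRecordError(f"{record.query_name}: deletion in MD {md!r}")
        return mm
    raise ValueError(f"{record.query_name}: neither NM nor MD tag present")


def read_sam(path: str | Path) -> tuple[list[Alignment], dict]:
    """Ingest SAM/BAM into Alignment records (read-orientation sequence,
    0-based starts); unmapped, indel and unscorable records are counted
    and skipped."""
    alignments: list[Alignment] = []
    stats = {"records": 0, "unmapped": 0, "indel": 0, "unscorable": 0}
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            stats["records"] += 1
            if rec.is_unmapped:
                stats["unmapped"] += 1
                continue
            try:
                mm = count_mismatches(rec)
            except UngappedRecordError:
                stats["indel"] += 1
                continue
            except ValueError:
                stats["unscorable"] += 1
                continue
            seq = rec.query_sequence
            strand = "-" if rec.is_reverse else "+"
            alignments.append(
                Alignment(
                    read_id=rec.query_name,
                    reference=rec.reference_name,
                    strand=strand,
                    start=rec.reference_start,
                    sequence=revcomp(seq) if rec.is_reverse else seq,
                    mismatches=mm,
                )
            )
    return alignments, stats


# ------------------------------------------------------------------- filter

def min_mismatch_filter(alignments: Iterable[Alignment]) -> list[Alignment]:
    """Per read, retain exactly the alignments with that read's minimum
    mismatch count. Identical placements (same reference, strand, start)
    are collapsed, with the number of collapsed duplicates logged."""
    by_read: dict[str, list[Alignment]] = defaultdict(list)
    for aln in alignments:
        by_read[aln.read_id].append(aln)
    retained: list[Alignment] = []
    n_dup = 0
    for alns in by_read.values():
        k_star = min(a.mismatches for a in alns)
        seen: set[tuple] = set()
        for a in alns:
            if a.mismatches != k_star:
                continue
            key = (a.reference, a.strand, a.start)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            retained.append(a)
    if n_dup:
        logger.info("min_mismatch_filter: collapsed %d duplicate placements", n_dup)
    return retained


def multiplicity_table(alignments: Sequence[Alignment]):
    """Per-read retained-alignment multiplicities as a DataFrame."""
    import pandas as pd

    counts: dict[str, int] = defaultdict(int)
    for a in alignments:
        counts[a.read_id] += 1
    return pd.DataFrame(
        sorted(counts.items()), columns=["read_id", "n_alignments"]
    )
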