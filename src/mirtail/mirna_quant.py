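"""Tag-to-miRNA assignment and CPM count tables.

A retained 18-26 nt tag is assigned to a mature miRNA when its
strand-aware 5' start lies within +/-3 nt of the annotated mature 5'
start on the same chromosome and strand. Raw counts are normalised to
counts per million: cpm = n * 1e6 / N, with N the trimmed library size.

A read whose retained alignments hit several matures contributes total
weight 1, split equally across its assignments (fractional counting);
``weighting="unique"`` instead drops multiply-assigned reads. Identical
matures annotated at several loci under one name are collapsed by name
before counting.
"""
from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .core import Alignment, MatureMirna

ASSIGN_WINDOW = 3
MIN_TAG_LENGTH = 18
MAX_TAG_LENGTH = 26


@dataclass(frozen=True)
class TagAssignment:
    read_id: str
    mirna_name: str
    offset5: int
    tag_length: int
    tag_sequence: str


class MirnaIndex:
    """Mature annotation indexed by (chromosome, strand, 5' start)."""

    def __init__(self, mirnas: Iterable[MatureMirna]):
        self.by_pos: dict[tuple[str, str, int], list[MatureMirna]] = defaultdict(list)
        self.by_name: dict[str, MatureMirna] = {}
        for m in mirnas:
            self.by_pos[(m.chromosome, m.strand, m.five_prime_start)].append(m)
            # multiple loci under one name: keep the first as representative
            self.by_name.setdefault(m.name, m)

    def candidates(self, chromosome: str, strand: str, tag5: int, window: int):
        for delta in range(-window, window + 1):
            for m in self.by_pos.get((chromosome, strand, tag5 - delta), ()):
                yield m


def assign_tag(
    alignment: Alignment,
    index: MirnaIndex,
    window: int = ASSIGN_WINDOW,
    min_length: int = MIN_TAG_LENGTH,
    max_length: int = MAX_TAG_LENGTH,
) -> list[TagAssignment]:
    """Assignments of one retained alignment under the 5'-window rule.

    offset5 is tag 5' start minus mature 5' start measured in transcript
    orientation, so a positive offset means the tag starts inside the
    mature sequence on either strand.
    """
    L = len(alignment.sequence)
    if not (min_length <= L <= max_length):
        return []
    tag5 = alignment.five_prime
    out = []
    for m in index.candidates(alignment.reference, alignment.strand, tag5, window):
        offset = tag5 - m.five_prime_start if m.strand == "+" else m.five_prime_start - tag5
        if abs(offset) <= window:
            out.append(TagAssignment(alignment.read_id, m.name, offset, L, alignment.sequence))
    return out


def assign_reads(
    alignments: Iterable[Alignment],
    index: MirnaIndex,
    window: int = ASSIGN_WINDOW,
    weighting: Literal["fractional", "unique"] = "fractional",
) -> pd.DataFrame:
    """Assign all retained alignments; one weighted table row per
    (read, miRNA name).

    Per read, assignments are collapsed by miRNA name (keeping the
    smallest |offset5|, ties to the smaller offset) and weighted to a
    total of 1; under ``unique`` weighting multiply-assigned reads are
    dropped.
    """
    per_read: dict[str, dict[str, TagAssignment]] = defaultdict(dict)
    for aln in alignments:
        for a in assign_tag(aln, index, window):
            prev = per_read[a.read_id].get(a.mirna_name)
            if prev is None or (abs(a.offset5), a.offset5) < (abs(prev.offset5), prev.offset5):
                per_read[a.read_id][a.mirna_name] = a
    rows = []
    for read_id, by_name in per_read.items():
        k = len(by_name)
        if weighting == "unique" and k > 1:
            continue
        w = 1.0 / k
        for a in by_name.values():
            rows.append(
                (read_id, a.mirna_name, a.offset5, a.tag_length, a.tag_sequence, w)
            )
    return pd.DataFrame(
        rows,
        columns=["read_id", "mirna_name", "offset5", "tag_length", "tag_sequence", "weight"],
    )


def build_count_table(
    assignments: pd.DataFrame,
    library_size: int,
    sample: str,
    all_mirnas: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-miRNA raw counts n and cpm = n * 1e6 / N for one sample."""
    if library_size == 0 and len(assignments):
        raise ValueError("library size N = 0 but assignments are present")
    counts = assignments.groupby("mirna_name")["weight"].sum() if len(assignments) else pd.Series(dtype=float)
    names = list(all_mirnas) if all_mirnas is not None else sorted(counts.index)
    n = np.array([float(counts.get(name, 0.0)) for name in names])
    cpm = n * 1_000_000 / library_size if library_size > 0 else np.full(len(n), np.nan)
    return pd.DataFrame(
        {"mirna_name": names, "sample": sample, "n": n, "N": library_size, "cpm": cpm}
    )


def expression_compare(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Per-miRNA CPM ratio (condition B over condition A); a zero
    denominator yields an undefined (NaN) ratio, flagged in ``defined``."""
    if set(table_a["mirna_name"]) != set(table_b["mirna_name"]):
        raise ValueError("count tables cover different annotation sets")
    a = table_a.set_index("mirna_name")["cpm"]
    b = table_b.set_index("mirna_name")["cpm"]
    out = pd.DataFrame({"cpm_a": a, "cpm_b": b.loc[a.index]})
    out["defined"] = out["cpm_a"] > 0
    out["ratio"] = np.where(out["defined"], out["cpm_b"] / out["cpm_a"].replace(0, np.nan), np.nan)
    return out.reset_index()
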