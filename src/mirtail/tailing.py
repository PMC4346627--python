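"""+1-nt 3'-tail classification and non-templated-addition percentages.

A canonical-start tag (5' offset 0) is classified against its mature
miRNA and the genome:

* exactly the mature sequence            -> ``exact_mature`` (class m)
* one nt longer, body identical to the mature, last base equal to the
  genome base at +1                      -> ``templated_extension``
* one nt longer, body identical, last base differing from the genome
  +1 base                                -> ``nta_A/C/G/U`` (T reported
  as U, RNA convention)
* anything else                          -> ``other``

The per-nucleotide NTA percentage is computed against the sum of mature
and all observable non-templated tags: for a genome +1 base of A the
non-templated-U percentage is t*100/(m+t+c+g). The nucleotide matching
the genome +1 base is unobservable as an NTA (an appended copy of it is
templated by definition) and is excluded from numerator and denominator;
templated extensions never enter the formula.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .core import Genome, MatureMirna, plus_one_base

NUCLEOTIDES = ("A", "C", "G", "U")
_DNA_TO_RNA = {"A": "A", "C": "C", "G": "G", "T": "U"}


class TagClass(enum.Enum):
    EXACT_MATURE = "exact_mature"
    TEMPLATED_EXTENSION = "templated_extension"
    NTA_A = "nta_A"
    NTA_C = "nta_C"
    NTA_G = "nta_G"
    NTA_U = "nta_U"
    OTHER = "other"


_NTA_BY_BASE = {
    "A": TagClass.NTA_A, "C": TagClass.NTA_C,
    "G": TagClass.NTA_G, "U": TagClass.NTA_U,
}


def classify_tag(tag_sequence: str, mature: MatureMirna, genome: Genome) -> TagClass:
    """Classify a canonical-start tag's 3' end.

    The caller guarantees offset5 = 0; the rule's requirement that the
    tag body be identical to the genome reference leaves no room for 5'
    offsets.
    """
    L = mature.length
    if tag_sequence == mature.sequence:
        return TagClass.EXACT_MATURE
    if len(tag_sequence) == L + 1 and tag_sequence[:L] == mature.sequence:
        templated = plus_one_base(genome, mature)
        if templated is None:
            return TagClass.OTHER  # +1 position off the contig
        last = tag_sequence[-1]
        if last == templated:
            return TagClass.TEMPLATED_EXTENSION
        if last not in _DNA_TO_RNA:
            return TagClass.OTHER  # ambiguous base call
        return _NTA_BY_BASE[_DNA_TO_RNA[last]]
    return TagClass.OTHER


@dataclass
class TailingProfile:
    """Per-miRNA, per-condition tail composition and percentages."""

    mirna_name: str
    condition: str
    templated_base: Optional[str]  # RNA letter; None if +1 off-contig
    m: int = 0
    templated: int = 0
    other: int = 0
    nta: dict[str, int] = field(default_factory=lambda: {n: 0 for n in NUCLEOTIDES})

    @property
    def observable(self) -> tuple[str, ...]:
        """NTA nucleotides distinguishable from a templated extension."""
        return tuple(n for n in NUCLEOTIDES if n != self.templated_base)

    @property
    def denominator(self) -> int:
        return self.m + sum(self.nta[n] for n in self.observable)

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    def pct(self, nucleotide: str) -> float:
        """Non-templated percentage for one nucleotide:
        count * 100 / (m + sum of observable NTA counts)."""
        if nucleotide not in self.observable:
            return math.nan  # unobservable as NTA (genome-templated base)
        if not self.defined:
            return math.nan
        return self.nta[nucleotide] * 100.0 / self.denominator

    @property
    def mono_u_pct(self) -> float:
        return self.pct("U")

    @property
    def mono_u_pct_vs_mature(self) -> float:
        """Alternative statistic: mono-uridylated per exactly matching
        mature tag, u * 100 / m."""
        if "U" not in self.observable or self.m == 0:
            return math.nan
        return self.nta["U"] * 100.0 / self.m

    def as_row(self) -> dict:
        row = {
            "mirna_name": self.mirna_name,
            "condition": self.condition,
            "templated_base": self.templated_base,
            "m": self.m,
            "templated": self.templated,
            "other": self.other,
            "denominator": self.denominator,
            "defined": self.defined,
        }
        for n in NUCLEOTIDES:
            row[n] = self.nta[n]
            row[f"pct_{n}"] = self.pct(n)
        row["mono_u_pct"] = self.mono_u_pct
        row["mono_u_pct_vs_mature"] = self.mono_u_pct_vs_mature
        return row


def profile_from_classes(
    classes: Iterable[TagClass],
    mirna_name: str,
    condition: str,
    templated_base: Optional[str],
) -> TailingProfile:
    prof = TailingProfile(mirna_name, condition, templated_base)
    for c in classes:
        if c is TagClass.EXACT_MATURE:
            prof.m += 1
        elif c is TagClass.TEMPLATED_EXTENSION:
            prof.templated += 1
        elif c is TagClass.OTHER:
            prof.other += 1
        else:
            prof.nta[c.value[-1]] += 1
    return prof


def profile_from_counts(
    mirna_name: str,
    condition: str,
    templated_base: Optional[str],
    m: int,
    nta: Mapping[str, int],
    templated: int = 0,
    other: int = 0,
) -> TailingProfile:
    """Build a profile directly from class counts (count-level input)."""
    prof = TailingProfile(mirna_name, condition, templated_base, m=m,
                          templated=templated, other=other)
    for n, c in nta.items():
        if c and templated_base is not None and n == templated_base:
            raise ValueError(
                f"{mirna_name}: NTA count for genome-templated base {n} is unobservable"
            )
        prof.nta[n] = int(c)
    return prof


def profiles_from_assignments(
    assignments: pd.DataFrame,
    mirnas: Iterable[MatureMirna],
    genome: Genome,
    condition: str,
    canonical_only: bool = True,
) -> list[TailingProfile]:
    """Classify assigned tags and aggregate per-miRNA profiles.

    Only canonical-start tags (offset5 = 0) are classified unless
    ``canonical_only`` is disabled for exploratory use.
    """
    by_name = {m.name: m for m in mirnas}
    rows = assignments
    if canonical_only:
        rows = rows[rows["offset5"] == 0]
    profiles = []
    for name, mature in by_name.items():
        sub = rows[rows["mirna_name"] == name]
        tb = plus_one_base(genome, mature)
        classes = (classify_tag(seq, mature, genome) for seq in sub["tag_sequence"])
        prof = profile_from_classes(classes, name, condition, _DNA_TO_RNA.get(tb) if tb else None)
        profiles.append(prof)
    return profiles


def profiles_to_frame(profiles: Iterable[TailingProfile]) -> pd.DataFrame:
    return pd.DataFrame([p.as_row() for p in profiles])


def plus_one_composition(profiles: pd.DataFrame) -> pd.DataFrame:
    """Distribution summary (median and quartiles) of per-miRNA NTA
    percentages at the +1 position, per condition and nucleotide."""
    rows = []
    for condition, sub in profiles.groupby("condition"):
        for n in NUCLEOTIDES:
            vals = sub[f"pct_{n}"].dropna()
            if not len(vals):
                continue
            rows.append(
                {
                    "condition": condition,
                    "nucleotide": n,
                    "n_mirnas": len(vals),
                    "q1": float(np.percentile(vals, 25)),
                    "median": float(np.median(vals)),
                    "q3": float(np.percentile(vals, 75)),
                }
            )
    return pd.DataFrame(rows)
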