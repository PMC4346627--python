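"""Shared domain types and sequence primitives.

Coordinates are 0-based half-open throughout the package; the GFF3
boundary (1-based closed) is converted in :mod:`mirtail.refio`.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def hamming(a: str, b: str) -> int:
    """Position-wise mismatch count of two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class Read:
    """A sequenced small-RNA tag."""

    read_id: str
    sequence: str
    quality: Optional[str] = None


@dataclass(frozen=True)
class Alignment:
    """One ungapped placement of a read on a reference.

    ``sequence`` is stored in read orientation (the 5'->3' sequence as
    sequenced); for minus-strand placements the reference-forward
    sequence is its reverse complement.
    """

    read_id: str
    reference: str
    strand: str  # '+' or '-'
    start: int  # 0-based half-open genomic start (leftmost)
    sequence: str
    mismatches: int

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the read's 5' nucleotide (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class MatureMirna:
    """An annotated mature miRNA locus.

    ``five_prime_start`` is the genomic coordinate (0-based) of the 5'
    nucleotide of the mature sequence; on the minus strand this is the
    larger coordinate of the span.
    """

    name: str
    chromosome: str
    strand: str
    five_prime_start: int
    sequence: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open genomic interval covered by the mature sequence."""
        if self.strand == "+":
            return (self.five_prime_start, self.five_prime_start + self.length)
        return (self.five_prime_start - self.length + 1, self.five_prime_start + 1)

    @property
    def plus_one_position(self) -> int:
        """Genomic coordinate of the base immediately 3' of the mature end."""
        if self.strand == "+":
            return self.five_prime_start + self.length
        return self.five_prime_start - self.length


class Genome:
    """In-memory genome: contig name -> uppercase sequence string."""

    def __init__(self, contigs: dict[str, str]):
        self.contigs = {name: seq.upper() for name, seq in contigs.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Strand-aware substring: '-' returns the reverse complement,
        i.e. the transcript-orientation sequence of a minus-strand feature."""
        if start < 0 or end > len(self.contigs[contig]):
            raise IndexError(
                f"[{start}, {end}) outside contig {contig} "
                f"(length {len(self.contigs[contig])})"
            )
        sub = self.contigs[contig][start:end]
        return revcomp(sub) if strand == "-" else sub

    def base_at(self, contig: str, pos: int) -> Optional[str]:
        seq = self.contigs.get(contig)
        if seq is None or not (0 <= pos < len(seq)):
            return None
        return seq[pos]


def plus_one_base(genome: Genome, mirna: MatureMirna) -> Optional[str]:
    """Transcript-orientation genome base at position +1 past the mature 3' end.

    This base decides which +1 tail nucleotide is genome-templated.
    Returns ``None`` when the position falls outside the contig.
    """
    base = genome.base_at(mirna.chromosome, mirna.plus_one_position)
    if base is None:
        return None
    return complement(base) if mirna.strand == "-" else base
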