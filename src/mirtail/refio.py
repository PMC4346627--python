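"""Reading and writing the standard formats at the package boundary.

FASTA/FASTQ go through Biopython, SAM through pysam, GFF3 through a
pandas table parse. GFF3 is 1-based closed; everything in memory is
0-based half-open.
"""
from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import Alignment, Genome, MatureMirna, revcomp

GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


# ---------------------------------------------------------------- FASTA/FASTQ

def write_fasta(sequences: dict[str, str] | Genome, path: str | Path) -> None:
    contigs = sequences.contigs if isinstance(sequences, Genome) else sequences
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_genome(path: str | Path) -> Genome:
    return Genome({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})


def write_fastq(reads: Iterable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = read.quality or "I" * len(read.sequence)
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")


def read_fastq(path: str | Path):
    from .core import Read

    return [
        Read(rec.id, str(rec.seq), "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]))
        for rec in SeqIO.parse(str(path), "fastq")
    ]


# --------------------------------------------------------------------- GFF3

def write_gff3(mirnas: Sequence[MatureMirna], path: str | Path, source: str = "mirtail") -> None:
    """Write mature miRNA records as GFF3 (1-based closed, Name attribute)."""
    lines = ["##gff-version 3"]
    for m in mirnas:
        start0, end0 = m.span
        lines.append(
            "\t".join(
                [
                    m.chromosome, source, "miRNA",
                    str(start0 + 1), str(end0),
                    ".", m.strand, ".",
                    f"ID={m.name};Name={m.name}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _attr_field(attributes: str, key: str) -> str:
    for part in attributes.split(";"):
        k, _, v = part.partition("=")
        if k.strip() == key:
            return v.strip()
    raise ValueError(f"GFF3 attribute {key!r} missing in {attributes!r}")


def read_gff3(path: str | Path, genome: Genome) -> list[MatureMirna]:
    """Load mature miRNA annotation; sequences are taken from the genome
    (strand-aware), which enforces the annotation/genome consistency the
    downstream +1-base lookup relies on."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GFF_COLUMNS,
        dtype={"seqid": str, "start": int, "end": int},
    )
    mirnas = []
    for row in df.itertuples(index=False):
        if row.seqid not in genome:
            raise ValueError(f"annotation chromosome {row.seqid!r} absent from genome")
        start0, end0 = row.start - 1, row.end  # GFF3 -> 0-based half-open
        five_prime = start0 if row.strand == "+" else end0 - 1
        seq = genome.fetch(row.seqid, start0, end0, row.strand)
        mirnas.append(
            MatureMirna(
                name=_attr_field(row.attributes, "Name"),
                chromosome=row.seqid,
                strand=row.strand,
                five_prime_start=five_prime,
                sequence=seq,
            )
        )
    return mirnas


def write_mature_fasta(mirnas: Sequence[MatureMirna], path: str | Path) -> None:
    write_fasta({m.name: m.sequence for m in mirnas}, path)


# ---------------------------------------------------------------------- SAM

def sam_header(genome: Genome) -> pysam.AlignmentHeader:
    names = list(genome.contigs)
    return pysam.AlignmentHeader.from_references(names, [len(genome[n]) for n in names])


def write_sam(alignments: Iterable[Alignment], genome: Genome, path: str | Path) -> None:
    """Write ungapped alignments as SAM with NM tags; minus-strand reads
    are stored reverse-complemented with the reverse flag set."""
    header = sam_header(genome)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = aln.read_id
            seg.flag = 16 if aln.strand == "-" else 0
            seg.reference_id = header.get_tid(aln.reference)
            seg.reference_start = aln.start
            seg.mapping_quality = 255
            seg.cigartuples = [(0, len(aln.sequence))]
            seg.query_sequence = revcomp(aln.sequence) if aln.strand == "-" else aln.sequence
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(aln.sequence))
            seg.set_tag("NM", aln.mismatches, "i")
            out.write(seg)
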