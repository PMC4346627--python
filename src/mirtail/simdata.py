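"""Synthetic small-RNA study generator.

Builds a toy genome with embedded mature-miRNA loci, miRBase-style
annotation, and two-condition read sets whose abundances, 5' offsets,
+1-nt 3' tails and sequencing errors are all recorded in a truth table,
so every downstream stage of the pipeline can be checked against known
ground truth.

Generative model
----------------
Per miRNA and condition the tag count is Poisson around a configured
mean. Each tag is the mature sequence shifted at the 5' end by an
offset in [-3, +3] (drawn from a configured distribution, restricted to
offsets that keep the tag length in [18, 26]), optionally extended by a
single 3' nucleotide, with the 3' adapter appended. The +1 nucleotide
is drawn by category: ``templated`` appends whatever the genome holds
at the +1 position; ``A/C/G/U`` appends that nucleotide. A drawn
nucleotide that happens to equal the genome +1 base is physically
indistinguishable from a templated extension and is recorded as
``templated`` in the truth table, so the truth labels always satisfy
the non-templated invariant.

Sequencing error is modelled per read: with probability ``error_rate``
one uniformly placed substitution is introduced into the insert
(adapter bases are left intact). Random streams are derived per miRNA
from the master seed, so adding miRNAs does not perturb existing ones.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core import Genome, MatureMirna, Read, plus_one_base, revcomp
from . import refio

DEFAULT_ADAPTER = "TCGTATGCCGTCTTCTGCTTGT"

TAIL_CLASSES = ("none", "templated", "A", "C", "G", "U")

#: default per-tag tail composition: tailing dominated by A and U, as in
#: typical mammalian small-RNA libraries.
DEFAULT_TAIL_PROBS = {
    "none": 0.70,
    "templated": 0.05,
    "A": 0.12,
    "C": 0.015,
    "G": 0.015,
    "U": 0.10,
}

#: default 5'-offset distribution: canonical 5' start dominates.
DEFAULT_OFFSET_PROBS = {0: 0.80, -1: 0.07, 1: 0.07, -2: 0.02, 2: 0.02, -3: 0.01, 3: 0.01}

_RNA_TO_DNA = {"A": "A", "C": "C", "G": "G", "U": "T"}
_DNA_TO_RNA = {"A": "A", "C": "C", "G": "G", "T": "U"}

TRUTH_COLUMNS = [
    "read_id", "condition", "mirna_name", "chromosome", "strand",
    "g_start", "offset5", "tail_class", "error_positions", "insert",
    "is_decoy",
]


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator."""

    n_mirnas: int = 20
    genome_length: int = 10_000
    conditions: tuple[str, ...] = ("wt", "mut")
    mean_abundance: float = 2500.0
    #: per-miRNA, per-condition overrides of the Poisson mean
    abundance: dict[str, dict[str, float]] = field(default_factory=dict)
    #: per-condition tail-class probabilities (defaults applied to all)
    tail_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    #: per-miRNA, per-condition tail-probability overrides
    tail_overrides: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    offset_probs: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_OFFSET_PROBS))
    error_rate: float = 0.001  # per-read probability of one substitution
    adapter: str = DEFAULT_ADAPTER
    rrna_decoy_fraction: float = 0.0
    mature_length_range: tuple[int, int] = (20, 23)
    seed: int = 0

    def tail_probs_for(self, mirna: str, condition: str) -> dict[str, float]:
        probs = dict(DEFAULT_TAIL_PROBS)
        probs.update(self.tail_probs.get(condition, {}))
        probs.update(self.tail_overrides.get(mirna, {}).get(condition, {}))
        return probs

    def abundance_for(self, mirna: str, condition: str) -> float:
        return self.abundance.get(mirna, {}).get(condition, self.mean_abundance)

    def mirna_names(self) -> list[str]:
        return [f"mir-sim-{i + 1:03d}" for i in range(self.n_mirnas)]

    def validate(self) -> None:
        if self.n_mirnas < 1:
            raise SimConfigError("n_mirnas must be >= 1")
        if not (0 <= self.error_rate < 1):
            raise SimConfigError("error_rate must be in [0, 1)")
        if not (0 <= self.rrna_decoy_fraction < 1):
            raise SimConfigError("rrna_decoy_fraction must be in [0, 1)")
        if set(self.adapter) - set("ACGT"):
            raise SimConfigError("adapter must be an ACGT string")
        lo, hi = self.mature_length_range
        if not (20 <= lo <= hi <= 23):
            raise SimConfigError("mature lengths must lie within [20, 23]")
        for name in self.mirna_names() + ["<default>"]:
            for cond in self.conditions:
                probs = self.tail_probs_for(name, cond)
                if set(probs) != set(TAIL_CLASSES):
                    raise SimConfigError(f"tail classes must be exactly {TAIL_CLASSES}")
                if any(p < 0 or p > 1 for p in probs.values()):
                    raise SimConfigError("tail probabilities must lie in [0, 1]")
                if not math.isclose(sum(probs.values()), 1.0, abs_tol=1e-9):
                    raise SimConfigError(
                        f"tail probabilities for {name}/{cond} must sum to 1"
                    )
        total_offset = sum(self.offset_probs.values())
        if any(o < -3 or o > 3 for o in self.offset_probs):
            raise SimConfigError("offsets must lie in [-3, 3]")
        if not math.isclose(total_offset, 1.0, abs_tol=1e-9):
            raise SimConfigError("offset probabilities must sum to 1")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


# ------------------------------------------------------------------ reference

def build_toy_reference(config: SimConfig) -> tuple[Genome, list[MatureMirna]]:
    """Random genome with non-overlapping embedded mature-miRNA loci.

    Strands alternate so that any config with ``n_mirnas >= 2`` exercises
    both orientations. Loci are padded so 5' offsets (+/-3) and the +1
    base never leave the contig, and separated so assignment windows of
    neighbouring loci cannot overlap.
    """
    config.validate()
    genome_rng = _rng(config.seed, 0)
    contig = "chr_sim"
    genome_seq = _random_sequence(genome_rng, config.genome_length)

    pad, gap = 10, 8
    occupied: list[tuple[int, int]] = []
    mirnas: list[MatureMirna] = []
    lo, hi = config.mature_length_range
    for i, name in enumerate(config.mirna_names()):
        rng = _rng(config.seed, 1, i)
        length = int(rng.integers(lo, hi + 1))
        strand = "+" if i % 2 == 0 else "-"
        upper = config.genome_length - length - pad
        if upper <= pad:
            raise SimConfigError("genome_length too small to place loci")
        for _ in range(1000):
            start = int(rng.integers(pad, upper))
            if all(start >= e + gap or start + length + gap <= s for s, e in occupied):
                break
        else:
            raise SimConfigError(
                f"could not place locus {name}; increase genome_length"
            )
        occupied.append((start, start + length))
        five_prime = start if strand == "+" else start + length - 1
        seq = Genome({contig: genome_seq}).fetch(contig, start, start + length, strand)
        mirnas.append(MatureMirna(name, contig, strand, five_prime, seq))

    contigs = {contig: genome_seq}
    if config.rrna_decoy_fraction > 0:
        decoy_rng = _rng(config.seed, 0, 99)
        contigs["rRNA_18S_decoy"] = _random_sequence(decoy_rng, 400)
        contigs["rRNA_28S_decoy"] = _random_sequence(decoy_rng, 600)
    return Genome(contigs), mirnas


def is_decoy_contig(name: str) -> bool:
    return name.endswith("_decoy")


# ---------------------------------------------------------------------- reads

def _valid_offsets(length: int, tailed: bool, probs: dict[int, float]) -> tuple[list[int], list[float]]:
    # tag length = mature_length - offset + tail must stay within [18, 26]
    t = 1 if tailed else 0
    valid = [o for o in probs if 18 <= length - o + t <= 26]
    if not valid:
        raise SimConfigError("no admissible 5' offset for this mature length")
    total = sum(probs[o] for o in valid)
    return valid, [probs[o] / total for o in valid]


def _insert_for(
    mirna: MatureMirna,
    genome: Genome,
    offset: int,
    tail_base_dna: str,
) -> tuple[str, int]:
    """Transcript-orientation insert and its leftmost genomic coordinate."""
    L, t = mirna.length, len(tail_base_dna)
    if mirna.strand == "+":
        start = mirna.five_prime_start + offset
        body = genome.fetch(mirna.chromosome, start, mirna.five_prime_start + L, "+")
        return body + tail_base_dna, start
    start = mirna.five_prime_start - L + 1 - t
    body = genome.fetch(
        mirna.chromosome, mirna.five_prime_start - L + 1,
        mirna.five_prime_start - offset + 1, "-",
    )
    return body + tail_base_dna, start


def simulate_reads(
    genome: Genome,
    mirnas: Iterable[MatureMirna],
    config: SimConfig,
) -> tuple[dict[str, list[Read]], pd.DataFrame]:
    """Two-condition read sets with a truth record for every read."""
    config.validate()
    mirnas = list(mirnas)
    reads: dict[str, list[Read]] = {cond: [] for cond in config.conditions}
    truth_rows: list[tuple] = []

    for ci, cond in enumerate(config.conditions):
        for mi, mirna in enumerate(mirnas):
            rng = _rng(config.seed, 2, mi, ci)
            count = int(rng.poisson(config.abundance_for(mirna.name, cond)))
            if count == 0:
                continue
            probs = config.tail_probs_for(mirna.name, cond)
            p_vec = [probs[c] for c in TAIL_CLASSES]
            tmpl = plus_one_base(genome, mirna)  # DNA letter or None
            classes = rng.choice(len(TAIL_CLASSES), size=count, p=p_vec)
            err_flags = rng.random(count) < config.error_rate
            for j in range(count):
                drawn = TAIL_CLASSES[classes[j]]
                if drawn == "none":
                    tail_dna, tail_class = "", "none"
                elif drawn == "templated":
                    if tmpl is None:
                        tail_dna, tail_class = "", "none"  # off-contig: untailed
                    else:
                        tail_dna, tail_class = tmpl, "templated"
                else:
                    tail_dna = _RNA_TO_DNA[drawn]
                    tail_class = "templated" if tail_dna == tmpl else drawn
                valid, vp = _valid_offsets(mirna.length, bool(tail_dna), config.offset_probs)
                offset = valid[rng.choice(len(valid), p=vp)]
                insert, g_start = _insert_for(mirna, genome, offset, tail_dna)
                err_pos = ""
                if err_flags[j]:
                    pos = int(rng.integers(0, len(insert)))
                    old = insert[pos]
                    new = "ACGT".replace(old, "")[int(rng.integers(0, 3))]
                    insert = insert[:pos] + new + insert[pos + 1:]
                    err_pos = str(pos)
                read_id = f"{cond}|{mirna.name}|{j:06d}"
                seq = insert + config.adapter
                reads[cond].append(Read(read_id, seq, "I" * len(seq)))
                truth_rows.append(
                    (read_id, cond, mirna.name, mirna.chromosome, mirna.strand,
                     g_start, offset, tail_class, err_pos, insert, False)
                )

        if config.rrna_decoy_fraction > 0:
            n_mirna_reads = len(reads[cond])
            decoy_rng = _rng(config.seed, 3, ci)
            f = config.rrna_decoy_fraction
            n_decoy = int(decoy_rng.binomial(n_mirna_reads, f / (1 - f)))
            decoy_names = [c for c in genome.contigs if is_decoy_contig(c)]
            for j in range(n_decoy):
                contig = decoy_names[int(decoy_rng.integers(0, len(decoy_names)))]
                length = int(decoy_rng.integers(18, 27))
                start = int(decoy_rng.integers(0, len(genome[contig]) - length))
                strand = "+-"[int(decoy_rng.integers(0, 2))]
                insert = genome.fetch(contig, start, start + length, strand)
                read_id = f"{cond}|decoy|{j:06d}"
                seq = insert + config.adapter
                reads[cond].append(Read(read_id, seq, "I" * len(seq)))
                truth_rows.append(
                    (read_id, cond, contig, contig, strand,
                     start, 0, "none", "", insert, True)
                )

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return reads, truth


# ----------------------------------------------------------------------- SAM

def emit_sam(
    truth: pd.DataFrame,
    genome: Genome,
    path: str | Path,
    condition: Optional[str] = None,
    exhaustive: bool = False,
    max_mismatches: int = 3,
) -> list:
    """Write alignments for simulated reads directly from the truth table,
    bypassing trimming and alignment for desk-scale tests.

    Each read gets its true placement; with ``exhaustive`` every other
    placement with <= ``max_mismatches`` substitutions is added by brute
    force. Mismatch counts are recomputed position-wise against the
    genome, so injected errors and non-templated tails are counted
    faithfully.
    """
    from .align_filter import toy_align
    from .core import Alignment, hamming

    rows = truth if condition is None else truth[truth["condition"] == condition]
    alignments: list[Alignment] = []
    for row in rows.itertuples(index=False):
        ref_sub = genome.fetch(
            row.chromosome, row.g_start, row.g_start + len(row.insert), row.strand
        )
        aln = Alignment(
            read_id=row.read_id, reference=row.chromosome, strand=row.strand,
            start=row.g_start, sequence=row.insert,
            mismatches=hamming(row.insert, ref_sub),
        )
        alignments.append(aln)
        if exhaustive:
            for extra in toy_align(
                [Read(row.read_id, row.insert)], genome, max_mismatches
            ):
                if (extra.reference, extra.strand, extra.start) != (
                    aln.reference, aln.strand, aln.start
                ):
                    alignments.append(extra)
    refio.write_sam(alignments, genome, path)
    return alignments


# --------------------------------------------------- count-level tail sampler

def simulate_tailing_counts(config: SimConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Draw per-miRNA +1-tail class counts from the generative model's
    count-level marginal (Poisson totals x multinomial classes), without
    materialising read sequences.

    Only canonical-start tags (offset 0) enter tailing profiles, so the
    Poisson mean is thinned by the offset-0 probability. A drawn
    nucleotide equal to the genome-templated base is folded into the
    templated class, exactly as in :func:`simulate_reads`. Columns:
    mirna_name, condition, templated_base (RNA letter), m, templated,
    A, C, G, U.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    p0 = config.offset_probs.get(0, 0.0)
    if p0 <= 0:
        raise SimConfigError("offset distribution gives no canonical-start tags")
    rows = []
    names = config.mirna_names()
    for ci, cond in enumerate(config.conditions):
        for mi, name in enumerate(names):
            rng = _rng(seed, 4, mi, ci)
            tmpl_rna = _DNA_TO_RNA["ACGT"[mi % 4]]  # fixed per-locus +1 base
            n0 = int(rng.poisson(config.abundance_for(name, cond) * p0))
            probs = config.tail_probs_for(name, cond)
            counts = rng.multinomial(n0, [probs[c] for c in TAIL_CLASSES])
            by_class = dict(zip(TAIL_CLASSES, (int(c) for c in counts)))
            templated = by_class["templated"] + by_class.pop(tmpl_rna)
            by_class[tmpl_rna] = 0
            rows.append(
                {
                    "mirna_name": name, "condition": cond,
                    "templated_base": tmpl_rna,
                    "m": by_class["none"], "templated": templated,
                    "A": by_class["A"], "C": by_class["C"],
                    "G": by_class["G"], "U": by_class["U"],
                }
            )
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- output

def write_simulation(
    config: SimConfig, outdir: str | Path
) -> tuple[Genome, list[MatureMirna], dict[str, list[Read]], pd.DataFrame]:
    """Run the generator and write genome FASTA, GFF3 + mature FASTA,
    per-condition FASTQ, per-condition SAM, and the truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, mirnas = build_toy_reference(config)
    reads, truth = simulate_reads(genome, mirnas, config)
    refio.write_fasta(genome, outdir / "genome.fa")
    refio.write_gff3(mirnas, outdir / "mirnas.gff3")
    refio.write_mature_fasta(mirnas, outdir / "mature.fa")
    for cond, rs in reads.items():
        refio.write_fastq(rs, outdir / f"reads_{cond}.fastq")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return genome, mirnas, reads, truth
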