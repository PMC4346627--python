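"""Adapter trimming and length filtering of raw small-RNA reads.

The trimmer scans the read left to right for the leftmost position
where a prefix of the 3' adapter matches with at least ``min_overlap``
aligned bases and a mismatch fraction at most ``max_mismatch_rate``,
and cuts everything from that position on. Reads shorter than
``min_length`` after trimming are discarded (MINLEN-style filter); the
library size N is the number of kept reads.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import Read, VALID_BASES
from .simdata import DEFAULT_ADAPTER

DEFAULT_MIN_LENGTH = 18
DEFAULT_MIN_OVERLAP = 6
DEFAULT_MAX_MISMATCH_RATE = 0.1


@dataclass(frozen=True)
class TrimResult:
    read: Read
    trimmed: str
    adapter_found: bool
    kept: bool

    @property
    def trimmed_length(self) -> int:
        return len(self.trimmed)


def _capped_mismatches(a: str, b: str, cap: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > cap:
                return mm
    return mm


def trim_adapter(
    read: Read,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> TrimResult:
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    seq = read.sequence
    if set(seq) - VALID_BASES:
        bad = sorted(set(seq) - VALID_BASES)
        raise ValueError(f"read {read.read_id}: non-ACGTN characters {bad}")

    cut = None
    for i in range(len(seq) - min_overlap + 1):
        overlap = min(len(adapter), len(seq) - i)
        cap = int(max_mismatch_rate * overlap + 1e-9)
        if _capped_mismatches(seq[i:i + overlap], adapter[:overlap], cap) <= cap:
            cut = i
            break
    trimmed = seq if cut is None else seq[:cut]
    return TrimResult(
        read=read,
        trimmed=trimmed,
        adapter_found=cut is not None,
        kept=len(trimmed) >= min_length,
    )


def trim_reads(
    reads: Iterable[Read],
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> tuple[list[Read], dict]:
    """Trim a read set; returns (kept trimmed reads, summary stats)."""
    kept: list[Read] = []
    n_in = n_adapter = 0
    for read in reads:
        n_in += 1
        res = trim_adapter(read, adapter, min_overlap, max_mismatch_rate, min_length)
        n_adapter += res.adapter_found
        if res.kept:
            qual = read.quality[: len(res.trimmed)] if read.quality else None
            kept.append(Read(read.read_id, res.trimmed, qual))
    stats = {
        "reads_in": n_in,
        "reads_kept": len(kept),
        "adapter_found": n_adapter,
        "N": len(kept),
    }
    return kept, stats


def length_histogram(reads: Iterable[Read]) -> Counter:
    """Exact read-length counts of kept (trimmed) reads."""
    return Counter(len(r.sequence) for r in reads)


def length_summary(hist: Counter) -> dict[str, int]:
    """Histogram binned to the assignable 18-26 nt range with
    out-of-range bins."""
    out: dict[str, int] = {"under_18": 0, "over_26": 0}
    for L in range(18, 27):
        out[str(L)] = hist.get(L, 0)
    for L, c in hist.items():
        if L < 18:
            out["under_18"] += c
        elif L > 26:
            out["over_26"] += c
    return out


def library_size(kept_reads: Sequence[Read]) -> int:
    """Library size N: number of reads kept after trimming and MINLEN."""
    return len(kept_reads)
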