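"""Read-level quality control for small RNA-seq libraries.

The cleaning cascade mirrors standard small-RNA practice: cut the 3' adapter,
keep inserts of mature-miRNA size (18-25 nt inclusive), drop reads with
unknown bases or poor base quality (at least 80 % of bases at Q >= 30), and
collapse identical clean reads to unique tags whose header carries the tag
frequency.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO

import numpy as np
from Bio import SeqIO

from .records import MatureRecord


@dataclass(frozen=True)
class Read:
    """A single sequencing read with per-base Phred scores."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and quality lengths differ")
        if self.qualities and not all(0 <= q <= 93 for q in self.qualities):
            raise ValueError("Phred scores must lie in [0, 93]")


@dataclass
class TagSet:
    """Unique clean-read sequences with their occurrence counts."""

    counts: dict[str, int]
    library: str = ""

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def read_fastq(handle: TextIO | str) -> Iterator[Read]:
    """Iterate a Sanger-encoded (Phred+33) FASTQ file as Read objects."""
    for rec in SeqIO.parse(handle, "fastq"):
        yield Read(
            id=rec.id,
            sequence=str(rec.seq).upper(),
            qualities=tuple(rec.letter_annotations["phred_quality"]),
        )


def trim_adapter(
    read: Read,
    adapter: str,
    min_overlap: int = 5,
    max_error_rate: float = 0.1,
) -> Read:
    """Cut the 3' adapter from a read, qualities in lockstep.

    The best adapter occurrence is searched as a semi-global match: a full
    internal occurrence of the adapter prefix, or a suffix of the read
    overlapping the adapter start.  Occurrences need >= ``min_overlap`` nt of
    adapter and a mismatch fraction <= ``max_error_rate``.  If none is found
    the read is returned unchanged (an untrimmed 50-bp read can never pass the
    18-25 nt size selection, so it falls out downstream).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = read.sequence
    adapter = adapter.upper()
    n, a = len(seq), len(adapter)
    if n < min_overlap:
        return read
    # Score every candidate start at once: pad the read so each start has a
    # full-width window, count mismatches over the true overlap only.
    # Preference: most matched adapter bases (as score-based trimmers do),
    # then lowest error rate, then leftmost start — a spurious internal
    # 5-mer cannot outrank the true full-length site.
    padded = np.frombuffer((seq + "\0" * a).encode("ascii"), dtype=np.uint8)
    ad = np.frombuffer(adapter.encode("ascii"), dtype=np.uint8)
    starts = np.arange(0, n - min_overlap + 1)
    windows = np.lib.stride_tricks.sliding_window_view(padded, a)[starts]
    overlap = np.minimum(a, n - starts)
    in_overlap = np.arange(a) < overlap[:, None]
    errors = ((windows != ad) & in_overlap).sum(axis=1)
    rate = errors / overlap
    valid = rate <= max_error_rate
    if not valid.any():
        return read
    matches = overlap - errors
    order = np.lexsort((starts[valid], rate[valid], -matches[valid]))
    cut = int(starts[valid][order[0]])
    return Read(id=read.id, sequence=seq[:cut], qualities=read.qualities[:cut])


def length_filter(sequence: str, min_len: int = 18, max_len: int = 25) -> bool:
    """Keep inserts of mature-miRNA size (bounds inclusive)."""
    return min_len <= len(sequence) <= max_len


def quality_filter(
    read: Read, min_q: int = 30, min_frac: float = 0.8, strict: bool = False
) -> bool:
    """Reject reads with N's or with too few high-quality bases.

    A base is high quality when its Phred score is >= ``min_q`` (or strictly
    greater with ``strict=True``); the read passes when at least ``min_frac``
    of its bases are high quality.
    """
    if "N" in read.sequence:
        return False
    if not read.qualities:
        return False
    if strict:
        good = sum(1 for q in read.qualities if q > min_q)
    else:
        good = sum(1 for q in read.qualities if q >= min_q)
    return good / len(read.qualities) >= min_frac


def clean_reads(
    reads: Iterable[Read],
    adapter: str,
    min_len: int = 18,
    max_len: int = 25,
    min_q: int = 30,
    min_frac: float = 0.8,
) -> Iterator[Read]:
    """Apply the full cascade: trim -> length selection -> quality filter."""
    for read in reads:
        trimmed = trim_adapter(read, adapter)
        if not length_filter(trimmed.sequence, min_len, max_len):
            continue
        if not quality_filter(trimmed, min_q, min_frac):
            continue
        yield trimmed


def collapse_reads(reads: Iterable[Read | str], library: str = "") -> TagSet:
    """Compress identical clean reads to unique tags with frequencies."""
    counter: Counter[str] = Counter(
        r.sequence if isinstance(r, Read) else r for r in reads
    )
    return TagSet(counts=dict(counter), library=library)


def filter_candidates(
    records: Iterable[MatureRecord], min_count: int = 5
) -> list[MatureRecord]:
    """Drop unreliable candidates: those observed fewer than 5 times."""
    return [r for r in records if r.count >= min_count]


def write_collapsed_fasta(tags: TagSet, handle: TextIO) -> None:
    """Write unique tags as ``>{tag_id}_x{count}`` FASTA entries.

    Tags are ordered by descending count then sequence for determinism.
    """
    ordered = sorted(tags.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    for i, (seq, count) in enumerate(ordered, start=1):
        prefix = f"{tags.library}_" if tags.library else ""
        handle.write(f">{prefix}tag{i}_x{count}\n{seq}\n")


def tagset_to_records(tags: TagSet) -> list[MatureRecord]:
    """Unique tags as MatureRecord candidates, ordered as in the FASTA."""
    ordered = sorted(tags.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    prefix = f"{tags.library}_" if tags.library else ""
    return [
        MatureRecord(
            id=f"{prefix}tag{i}", sequence=seq, library=tags.library, count=c
        )
        for i, (seq, c) in enumerate(ordered, start=1)
    ]


__all__ = [
    "Read",
    "TagSet",
    "clean_reads",
    "collapse_reads",
    "filter_candidates",
    "length_filter",
    "quality_filter",
    "read_fastq",
    "tagset_to_records",
    "trim_adapter",
    "write_collapsed_fasta",
]
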