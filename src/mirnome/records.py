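"""Core domain records shared across the pipeline stages.

Sequences are normalized to the DNA alphabet internally (U -> T, upper case);
seeds are reported lower-case in the RNA alphabet, matching the convention of
miRNA catalogues ("gaggua" style).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_dna(sequence: str) -> str:
    """Upper-case a nucleotide string and convert RNA U to DNA T."""
    return sequence.upper().replace("U", "T")


def reverse_complement(sequence: str) -> str:
    return normalize_dna(sequence).translate(_COMPLEMENT)[::-1]


def to_rna_lower(sequence: str) -> str:
    """DNA string -> lower-case RNA, the reporting convention for seeds."""
    return normalize_dna(sequence).replace("T", "U").lower()


def extract_seed(sequence: str) -> str:
    """Seed region of a mature miRNA: bases 2-7 (1-based, inclusive).

    The seed is the primary determinant of target binding and is returned
    lower-case in the RNA alphabet.  Sequences shorter than 7 nt cannot carry
    a full seed and raise ``ValueError``.
    """
    if len(sequence) < 7:
        raise ValueError(
            f"sequence of length {len(sequence)} is too short for a 2-7 seed"
        )
    return to_rna_lower(sequence[1:7])


@dataclass(frozen=True)
class MatureRecord:
    """One mature miRNA sequence with its library of origin and tag count."""

    id: str
    sequence: str
    library: str = ""
    count: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_dna(self.sequence))

    @property
    def seed(self) -> str:
        return extract_seed(self.sequence)


@dataclass(frozen=True)
class AlignmentResult:
    """End-free pairwise alignment summary for two short sequences.

    ``mismatches`` counts substitutions plus indels on the optimal path;
    overhangs are the unaligned lengths at the 5' and 3' ends (the maximum of
    the two sequences' unaligned ends on that side).
    """

    query_id: str
    subject_id: str
    mismatches: int
    overhang_5: int
    overhang_3: int
    aligned_len: int
    matches: int = 0
    query_unaligned_5: int = 0
    query_unaligned_3: int = 0
    subject_unaligned_5: int = 0
    subject_unaligned_3: int = 0
    query_len: int = 0
    subject_len: int = 0

    @property
    def identity(self) -> float:
        """Fraction of aligned columns that are exact matches."""
        if self.aligned_len == 0:
            return 0.0
        return self.matches / self.aligned_len

    def coverage_of(self, which: str) -> float:
        """Aligned fraction of one sequence ("query" or "subject")."""
        if which == "query":
            total, u5, u3 = self.query_len, self.query_unaligned_5, self.query_unaligned_3
        elif which == "subject":
            total, u5, u3 = self.subject_len, self.subject_unaligned_5, self.subject_unaligned_3
        else:
            raise ValueError("which must be 'query' or 'subject'")
        if total == 0:
            return 0.0
        return (total - u5 - u3) / total

    @property
    def longer_coverage(self) -> float:
        """Aligned fraction of the longer of the two sequences."""
        if self.query_len >= self.subject_len:
            return self.coverage_of("query")
        return self.coverage_of("subject")


class MatchCategory(str, Enum):
    """Three-way homology classification of a database hit."""

    ENTIRE_MATCH = "entire_match"
    MISMATCH = "mismatch"
    NO_HIT = "no_hit"


class GroupKind(str, Enum):
    PARALOG = "paralog"
    ORTHOLOG = "ortholog"


@dataclass
class SequenceGroup:
    """A paralog or ortholog group of mature miRNA records."""

    group_id: str
    members: list[MatureRecord]
    kind: GroupKind
    shared_seed: str | None = None
    expression: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a SequenceGroup needs at least one member")

    @property
    def libraries(self) -> set[str]:
        return {m.library for m in self.members}

    def members_in(self, library: str) -> list[MatureRecord]:
        return [m for m in self.members if m.library == library]


@dataclass
class CountMatrix:
    """Features x libraries non-negative counts with a library->species map."""

    counts: pd.DataFrame
    species: dict[str, str]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("count matrix has negative entries")
        missing = set(self.counts.columns) - set(self.species)
        if missing:
            raise ValueError(f"libraries without a species label: {sorted(missing)}")

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    def libraries_of(self, species: str) -> list[str]:
        return [l for l in self.counts.columns if self.species[l] == species]

    def with_counts(self, counts: pd.DataFrame) -> "CountMatrix":
        return CountMatrix(counts=counts, species=dict(self.species))


class LocusClass(str, Enum):
    EXONIC = "exonic"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    EXON_INTRON_BOUNDARY = "exon_intron_boundary"


@dataclass(frozen=True)
class GenomicHit:
    """An ungapped placement of a precursor on a genome (0-based half-open)."""

    query_id: str
    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("invalid hit coordinates")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.mismatches < 0:
            raise ValueError("negative mismatch count")


@dataclass(frozen=True)
class TargetHit:
    """An exact 6-mer seed-complement match of a miRNA in a 3'-UTR."""

    mirna_id: str
    gene_id: str
    position: int
    match_class: str = "6mer"


__all__ = [
    "AlignmentResult",
    "CountMatrix",
    "GenomicHit",
    "GroupKind",
    "LocusClass",
    "MatchCategory",
    "MatureRecord",
    "SequenceGroup",
    "TargetHit",
    "extract_seed",
    "normalize_dna",
    "reverse_complement",
    "to_rna_lower",
]
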