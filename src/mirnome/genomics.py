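"""Precursor-to-genome mapping and genomic locus classification.

Mapping is ungapped: every placement of the query on either strand with at
most ``max_mismatches`` substitutions is reported, which reproduces the
semantics of short-read mappers run in ungapped (-v) mode on the desk-scale
genomes this package targets.  Each mapped precursor is classified as
exonic, intronic, intergenic or exon/intron-boundary against a strand-aware
exon annotation, and precursors absent from every foreign genome (at the
3-mismatch allowance) are called species-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
from Bio import SeqIO

from .records import GenomicHit, LocusClass, normalize_dna, reverse_complement

logger = logging.getLogger(__name__)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def read_genome(source: str | TextIO | Mapping[str, str]) -> dict[str, str]:
    """Load a genome as chrom -> sequence (FASTA path/handle or mapping)."""
    if isinstance(source, Mapping):
        return {c: normalize_dna(s) for c, s in source.items()}
    return {
        rec.id: normalize_dna(str(rec.seq)) for rec in SeqIO.parse(source, "fasta")
    }


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _scan_strand(query: str, chrom_seq: np.ndarray, max_mismatches: int) -> list[tuple[int, int]]:
    """All (start, mismatches) of an ungapped placement on one strand."""
    q = _encode(query)
    n, k = len(chrom_seq), len(q)
    if k > n:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(chrom_seq, k)
    mismatches = (windows != q).sum(axis=1)
    hits = np.nonzero(mismatches <= max_mismatches)[0]
    return [(int(i), int(mismatches[i])) for i in hits]


def map_sequence(
    query: str,
    genome: Mapping[str, str],
    max_mismatches: int = 0,
    query_id: str = "query",
) -> list[GenomicHit]:
    """Ungapped occurrences of ``query`` on both strands of ``genome``.

    Hits are sorted by mismatch count, then chromosome, coordinate and
    strand ('+' before '-').
    """
    if not 0 <= max_mismatches <= 3:
        raise ValueError("max_mismatches must be in 0..3")
    q_fwd = normalize_dna(query)
    q_rev = reverse_complement(q_fwd)
    hits: list[GenomicHit] = []
    for chrom in sorted(genome):
        enc = _encode(normalize_dna(genome[chrom]))
        for strand, q in (("+", q_fwd), ("-", q_rev)):
            for start, mm in _scan_strand(q, enc, max_mismatches):
                hits.append(
                    GenomicHit(
                        query_id=query_id,
                        chrom=chrom,
                        start=start,
                        end=start + len(q),
                        strand=strand,
                        mismatches=mm,
                    )
                )
    hits.sort(key=lambda h: (h.mismatches, h.chrom, h.start, h.strand))
    return hits


@dataclass(frozen=True)
class Feature:
    """One exon or intron interval of a gene (0-based half-open)."""

    chrom: str
    start: int
    end: int
    gene: str
    strand: str


@dataclass
class GeneAnnotation:
    """Strand-aware exon/intron annotation built from per-gene exons."""

    exons: list[Feature] = field(default_factory=list)
    introns: list[Feature] = field(default_factory=list)

    @classmethod
    def from_exons(cls, exons: Iterable[Feature]) -> "GeneAnnotation":
        """Derive introns as the gaps between a gene's sorted exons."""
        exons = sorted(exons, key=lambda f: (f.chrom, f.gene, f.start))
        introns: list[Feature] = []
        by_gene: dict[tuple[str, str, str], list[Feature]] = {}
        for e in exons:
            by_gene.setdefault((e.chrom, e.gene, e.strand), []).append(e)
        for (chrom, gene, strand), gene_exons in by_gene.items():
            for a, b in zip(gene_exons, gene_exons[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping exons in gene {gene}: "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )
                if b.start > a.end:
                    introns.append(Feature(chrom, a.end, b.start, gene, strand))
        return cls(exons=list(exons), introns=introns)

    @classmethod
    def from_bed(cls, handle: TextIO | str) -> "GeneAnnotation":
        """Read exons from BED6 (name column = gene id)."""
        if isinstance(handle, str):
            with open(handle) as fh:
                return cls.from_bed(fh)
        exons = []
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5] if len(fields) > 5 else "+"
            exons.append(Feature(chrom, start, end, name, strand))
        return cls.from_exons(exons)


def _overlapping(features: Sequence[Feature], hit: GenomicHit) -> list[Feature]:
    return [
        f
        for f in features
        if f.chrom == hit.chrom
        and f.strand == hit.strand
        and f.start < hit.end
        and hit.start < f.end
    ]


def _covered_by(hit: GenomicHit, features: Sequence[Feature]) -> bool:
    """True when [hit.start, hit.end) lies entirely in the interval union."""
    intervals = sorted((f.start, f.end) for f in features)
    pos = hit.start
    for start, end in intervals:
        if start > pos:
            return False
        pos = max(pos, end)
        if pos >= hit.end:
            return True
    return pos >= hit.end


def classify_locus(hit: GenomicHit, annotation: GeneAnnotation) -> LocusClass:
    """Locate a mapped precursor relative to the gene annotation.

    Priority when isoforms or neighbouring genes disagree:
    exonic > exon/intron boundary > intronic; a hit touching no gene feature
    is intergenic.
    """
    for e in annotation.exons:
        for i in annotation.introns:
            if (
                e.gene == i.gene
                and e.chrom == i.chrom
                and e.strand == i.strand
                and e.start < i.end
                and i.start < e.end
            ):
                raise ValueError(
                    f"inconsistent annotation: exon and intron of gene {e.gene} overlap"
                )
    exons = _overlapping(annotation.exons, hit)
    introns = _overlapping(annotation.introns, hit)
    if not exons and not introns:
        return LocusClass.INTERGENIC
    if exons and _covered_by(hit, exons):
        return LocusClass.EXONIC
    for e in exons:
        for i in introns:
            if e.gene == i.gene and (e.end == i.start or i.end == e.start):
                return LocusClass.EXON_INTRON_BOUNDARY
    if introns and _covered_by(hit, introns):
        return LocusClass.INTRONIC
    # partial overlap at a gene edge: no rule in the three-way scheme fits
    # exactly; fall back by what is touched, preferring the exonic call
    logger.debug("hit %s partially overlaps a gene edge", hit)
    if exons:
        return LocusClass.EXONIC
    return LocusClass.INTRONIC


def classify_precursor_loci(
    hits_by_query: Mapping[str, Sequence[GenomicHit]],
    annotation: GeneAnnotation,
) -> dict[str, LocusClass]:
    """Classify each precursor by its best hit (fewest mismatches, then
    lowest coordinate)."""
    classes: dict[str, LocusClass] = {}
    for query_id, hits in hits_by_query.items():
        if not hits:
            continue
        best = min(hits, key=lambda h: (h.mismatches, h.chrom, h.start, h.strand))
        classes[query_id] = classify_locus(best, annotation)
    return classes


def call_species_specific(
    precursors: Mapping[str, str],
    foreign_genomes: Mapping[str, Mapping[str, str]],
    max_mismatches: int = 3,
) -> set[str]:
    """Precursors with no acceptable-mismatch placement in ANY foreign genome.

    A precursor mapping (either strand, <= ``max_mismatches`` substitutions)
    to even one foreign genome is conserved there and excluded.
    """
    if not foreign_genomes:
        raise ValueError("need at least one foreign genome")
    specific: set[str] = set()
    for pid, seq in precursors.items():
        mapped_somewhere = False
        for genome in foreign_genomes.values():
            if map_sequence(seq, genome, max_mismatches, query_id=pid):
                mapped_somewhere = True
                break
        if not mapped_somewhere:
            specific.add(pid)
    return specific


__all__ = [
    "Feature",
    "GeneAnnotation",
    "call_species_specific",
    "classify_locus",
    "classify_precursor_loci",
    "map_sequence",
    "read_genome",
]
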