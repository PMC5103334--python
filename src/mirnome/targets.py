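"""Seed-match target prediction and GO term enrichment of target genes.

Target sites are canonical 6-mers: every exact, sense-strand occurrence of
the reverse complement of a miRNA's seed (bases 2-7) in a 3'-UTR is a
predicted site.  Enrichment of a target gene set against a background is a
one-sided Fisher exact test per GO term with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd
from Bio import SeqIO
from scipy import stats

from .records import MatureRecord, TargetHit, normalize_dna, reverse_complement
from .diffexpr import bh_adjust


def read_utrs(source: str | TextIO | Mapping[str, str]) -> dict[str, str]:
    """Load 3'-UTR sequences as gene id -> DNA sequence."""
    if isinstance(source, Mapping):
        return {g: normalize_dna(s) for g, s in source.items()}
    return {r.id: normalize_dna(str(r.seq)) for r in SeqIO.parse(source, "fasta")}


def filter_utrs(utrs: Mapping[str, str], min_len: int = 20) -> dict[str, str]:
    """Discard UTRs shorter than ``min_len`` (too short to be scanned)."""
    return {g: s for g, s in utrs.items() if len(s) >= min_len}


def seed_target_scan(
    mirnas: Iterable[MatureRecord], utrs: Mapping[str, str]
) -> list[TargetHit]:
    """All exact seed-complement 6-mer sites of each miRNA in each UTR."""
    hits: list[TargetHit] = []
    for rec in mirnas:
        site = reverse_complement(rec.seed)
        for gene in sorted(utrs):
            seq = utrs[gene]
            pos = seq.find(site)
            while pos != -1:
                hits.append(TargetHit(mirna_id=rec.id, gene_id=gene, position=pos))
                pos = seq.find(site, pos + 1)
    return hits


def fisher_go_enrichment(
    target_genes: Iterable[str],
    background: Iterable[str],
    go_map: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Per-term over-representation of targets in the background.

    For each GO term annotating at least one background gene, the 2x2 table
    (in target set x annotated to term) is tested one-sided (greater) by
    Fisher's exact test; p-values are BH-adjusted across all tested terms.
    Rows are sorted by FDR then term id.
    """
    targets = set(target_genes)
    bg = set(background)
    if not targets:
        raise ValueError("empty target set")
    if not targets <= bg:
        raise ValueError("target genes must be a subset of the background")
    term_genes: dict[str, set[str]] = {}
    for gene in bg:
        for term in go_map.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)
    rows = []
    n_bg = len(bg)
    n_t = len(targets)
    for term in sorted(term_genes):
        annotated = term_genes[term]
        k = len(annotated & targets)       # targets with the term
        m = len(annotated)                 # background genes with the term
        table = [[k, n_t - k], [m - k, n_bg - n_t - (m - k)]]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "term": term,
                "targets_annotated": k,
                "background_annotated": m,
                "targets_total": n_t,
                "background_total": n_bg,
                "pvalue": float(p),
            }
        )
    result = pd.DataFrame(rows)
    result["fdr"] = bh_adjust(result["pvalue"].to_numpy())
    return result.sort_values(["fdr", "term"]).reset_index(drop=True)


def export_network(
    hits: Iterable[TargetHit], de_mirnas: Iterable[str]
) -> pd.DataFrame:
    """Unique miRNA-gene edges restricted to differentially expressed miRNA.

    Multiple sites of one miRNA in one UTR collapse into a single edge;
    the edge list drives the interaction-network figure and its edge /
    unique-gene counts.
    """
    de = set(de_mirnas)
    edges = sorted({(h.mirna_id, h.gene_id) for h in hits if h.mirna_id in de})
    return pd.DataFrame(edges, columns=["mirna", "gene"])


__all__ = [
    "export_network",
    "filter_utrs",
    "fisher_go_enrichment",
    "read_utrs",
    "seed_target_scan",
]
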