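"""End-to-end workflows: miRNome identification/comparison and mRNA DE.

`run_mirnome_workflow` chains preprocess -> homology -> grouping -> genomics
-> differential expression -> targets over a directory of per-library FASTQ
files (plus optional precursor FASTA, genomes, annotation, reference
catalogue, UTRs and GO map), writing per-stage outputs and a reproducible
run manifest with input checksums and per-stage record counts.

`run_mrna_workflow` runs the ortholog count-matrix comparison: zero-row
exclusion -> TMM -> per-species-pair NB DE -> up/down intersection -> GO
enrichment -> per-term accumulated expression.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffexpr import (
    accumulate_go_expression,
    correlation_cluster,
    filter_expressed,
    intersect_de,
    nb_de_test,
    pca,
    quantile_normalize,
    tmm_factors,
)
from .genomics import GeneAnnotation, call_species_specific, classify_precursor_loci, map_sequence, read_genome
from .grouping import build_ortholog_groups
from .homology import classify_against_reference, find_novel_seeds
from .preprocess import (
    clean_reads,
    collapse_reads,
    filter_candidates,
    read_fastq,
    tagset_to_records,
    write_collapsed_fasta,
)
from .records import CountMatrix, MatureRecord, extract_seed
from .synthdata import DEFAULT_ADAPTER

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    input_dir: str
    output_dir: str
    seed: int = 0
    adapter: str = DEFAULT_ADAPTER
    min_len: int = 18
    max_len: int = 25
    min_q: int = 30
    min_frac: float = 0.8
    min_count: int = 5
    identity: float = 0.9
    coverage: float = 0.9
    max_mismatches: int = 3
    lfc_threshold: float = 2.0
    de_alpha_mirna: float = 0.01
    de_alpha_mrna: float = 0.05
    focal_species: str | None = None
    reference_fasta: str | None = None
    stages: tuple[str, ...] = (
        "preprocess",
        "homology",
        "grouping",
        "genomics",
        "diffexpr",
        "targets",
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if not Path(cfg.input_dir).exists():
            raise ValueError(f"input_dir does not exist: {cfg.input_dir}")
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class WorkflowResult:
    manifest: dict
    records: dict[str, list[MatureRecord]]
    groups: list
    conserved_matrix: CountMatrix | None
    de_tables: dict[str, pd.DataFrame]
    common_up: set[str]
    common_down: set[str]
    specific: set[str]
    locus_classes: dict[str, str]


def run_mirnome_workflow(config: RunConfig) -> WorkflowResult:
    """Run the small-RNA workflow over ``config.input_dir``.

    Expects ``{library}.fastq`` files (library named ``{species}_L{n}``) and
    optionally ``{species}.precursor.fa``, ``{species}.genome.fa`` and
    ``{species}.exons.bed``.  Returns all stage outputs plus the manifest,
    which is also written to ``output_dir``.
    """
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    fastqs = sorted(indir.glob("*.fastq"))
    if not fastqs:
        raise StageError("preprocess", FileNotFoundError("no *.fastq in input_dir"))
    manifest: dict = {
        "version": __version__,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items()
        },
        "inputs": {p.name: _sha256(p) for p in sorted(indir.glob("*")) if p.is_file()},
        "stages": {},
    }

    # --- preprocess --------------------------------------------------------
    records: dict[str, list[MatureRecord]] = {}
    try:
        n_raw = n_clean = 0
        for fq in fastqs:
            lib = fq.stem
            reads = list(read_fastq(str(fq)))
            n_raw += len(reads)
            cleaned = list(
                clean_reads(
                    reads,
                    config.adapter,
                    config.min_len,
                    config.max_len,
                    config.min_q,
                    config.min_frac,
                )
            )
            n_clean += len(cleaned)
            tags = collapse_reads(cleaned, library=lib)
            with open(outdir / f"{lib}.collapsed.fa", "w") as fh:
                write_collapsed_fasta(tags, fh)
            records[lib] = filter_candidates(
                tagset_to_records(tags), config.min_count
            )
        manifest["stages"]["preprocess"] = {
            "raw_reads": n_raw,
            "clean_reads": n_clean,
            "candidates": sum(len(v) for v in records.values()),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("preprocess", exc) from exc

    species_of = {lib: lib.split("_")[0] for lib in records}
    focal = config.focal_species or sorted(set(species_of.values()))[0]

    # --- homology ----------------------------------------------------------
    try:
        all_seeds = [r.seed for lib in sorted(records) for r in records[lib]]
        reference_seeds: list[str] = []
        category_counts: dict[str, int] = {}
        if config.reference_fasta:
            from Bio import SeqIO

            refs = [
                (rec.id, str(rec.seq))
                for rec in SeqIO.parse(config.reference_fasta, "fasta")
            ]
            reference_seeds = [extract_seed(seq) for _, seq in refs if len(seq) >= 7]
            focal_records = [
                r for lib in sorted(records) for r in records[lib]
                if species_of[r.library] == focal
            ]
            for r in focal_records:
                cat, _ = classify_against_reference(r.sequence, refs)
                category_counts[cat.value] = category_counts.get(cat.value, 0) + 1
        n_unique, repeated, novel = find_novel_seeds(all_seeds, reference_seeds)
        manifest["stages"]["homology"] = {
            "unique_seeds": n_unique,
            "repeated_seeds": len(repeated),
            "novel_seeds": len(novel),
            "categories": category_counts,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("homology", exc) from exc

    # --- grouping ----------------------------------------------------------
    try:
        groups = build_ortholog_groups(
            records, identity=config.identity, coverage=config.coverage
        )
        matrix = pd.DataFrame(
            {lib: [g.expression.get(lib, 0.0) for g in groups] for lib in sorted(records)},
            index=[g.group_id for g in groups],
        )
        conserved = CountMatrix(counts=matrix, species=species_of)
        matrix.to_csv(outdir / "conserved_matrix.tsv", sep="\t")
        with open(outdir / "groups.tsv", "w") as fh:
            fh.write("group_id\tshared_seed\tmembers\n")
            for g in groups:
                fh.write(
                    f"{g.group_id}\t{g.shared_seed}\t"
                    + ",".join(m.id for m in g.members) + "\n"
                )
        manifest["stages"]["grouping"] = {
            "conserved_groups": len(groups),
            "member_records": sum(len(g.members) for g in groups),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("grouping", exc) from exc

    # --- genomics ----------------------------------------------------------
    specific: set[str] = set()
    locus_classes: dict[str, str] = {}
    try:
        genome_files = {p.stem.split(".")[0]: p for p in indir.glob("*.genome.fa")}
        precursor_files = {p.stem.split(".")[0]: p for p in indir.glob("*.precursor.fa")}
        if genome_files and focal in precursor_files:
            from Bio import SeqIO

            focal_precursors = {
                rec.id: str(rec.seq)
                for rec in SeqIO.parse(str(precursor_files[focal]), "fasta")
            }
            foreign = {
                sp: read_genome(str(path))
                for sp, path in sorted(genome_files.items())
                if sp != focal
            }
            if foreign:
                specific = call_species_specific(
                    focal_precursors, foreign, config.max_mismatches
                )
            bed = indir / f"{focal}.exons.bed"
            if bed.exists() and focal in genome_files:
                annotation = GeneAnnotation.from_bed(str(bed))
                own = read_genome(str(genome_files[focal]))
                hits = {
                    pid: map_sequence(seq, own, config.max_mismatches, query_id=pid)
                    for pid, seq in sorted(focal_precursors.items())
                }
                locus_classes = {
                    pid: cls.value
                    for pid, cls in classify_precursor_loci(hits, annotation).items()
                }
            (outdir / "specific.txt").write_text(
                "".join(f"{pid}\n" for pid in sorted(specific))
            )
            pd.Series(locus_classes, name="locus").to_csv(
                outdir / "locus.tsv", sep="\t"
            )
        manifest["stages"]["genomics"] = {
            "specific": len(specific),
            "locus_classified": len(locus_classes),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("genomics", exc) from exc

    # --- differential expression -------------------------------------------
    de_tables: dict[str, pd.DataFrame] = {}
    common_up: set[str] = set()
    common_down: set[str] = set()
    try:
        other_species = sorted(set(species_of.values()) - {focal})
        count_matrix = conserved.counts.round().astype(int)
        if len(groups) >= 2 and other_species:
            calls = {}
            for sp in other_species:
                libs_other = [l for l in count_matrix.columns if species_of[l] == sp]
                libs_focal = [l for l in count_matrix.columns if species_of[l] == focal]
                res = nb_de_test(
                    count_matrix,
                    group_a=libs_other,
                    group_b=libs_focal,
                    lfc_threshold=config.lfc_threshold,
                    alpha=config.de_alpha_mirna,
                )
                de_tables[f"{focal}_vs_{sp}"] = res.table
                res.table.to_csv(outdir / f"de_{focal}_vs_{sp}.tsv", sep="\t")
                calls[sp] = res.calls()
            if len(calls) >= 2:
                common_up, common_down = intersect_de(calls)
            elif calls:
                only = next(iter(calls.values()))
                common_up = {f for f, c in only.items() if c == "up"}
                common_down = {f for f, c in only.items() if c == "down"}
            normalized = quantile_normalize(conserved)
            if len(groups) >= 3:
                correlation_cluster(normalized, axis="columns")
                pca(normalized)
        manifest["stages"]["diffexpr"] = {
            "comparisons": len(de_tables),
            "common_up": len(common_up),
            "common_down": len(common_down),
        }
        with open(outdir / "intersection.json", "w") as fh:
            json.dump(
                {"common_up": sorted(common_up), "common_down": sorted(common_down)},
                fh,
                indent=2,
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError("diffexpr", exc) from exc

    # --- targets -----------------------------------------------------------
    try:
        n_edges = 0
        utr_file = indir / "utrs.fa"
        if utr_file.exists() and (common_up or common_down):
            from .targets import filter_utrs, read_utrs, seed_target_scan, export_network

            utrs = filter_utrs(read_utrs(str(utr_file)))
            de_groups = [g for g in groups if g.group_id in common_up | common_down]
            de_records = [
                MatureRecord(id=g.group_id, sequence=g.members[0].sequence)
                for g in de_groups
            ]
            hits = seed_target_scan(de_records, utrs)
            network = export_network(hits, {g.group_id for g in de_groups})
            network.to_csv(outdir / "network.tsv", sep="\t", index=False)
            n_edges = len(network)
        manifest["stages"]["targets"] = {"network_edges": n_edges}
    except Exception as exc:  # noqa: BLE001
        raise StageError("targets", exc) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return WorkflowResult(
        manifest=manifest,
        records=records,
        groups=groups,
        conserved_matrix=conserved,
        de_tables=de_tables,
        common_up=common_up,
        common_down=common_down,
        specific=specific,
        locus_classes=locus_classes,
    )


@dataclass
class MrnaWorkflowResult:
    de_tables: dict[str, pd.DataFrame]
    common_up: set[str]
    common_down: set[str]
    enrichment_up: pd.DataFrame | None
    enrichment_down: pd.DataFrame | None
    accumulated: pd.DataFrame | None
    tmm: pd.Series


def run_mrna_workflow(
    matrix: CountMatrix,
    focal_species: str,
    go_map: Mapping[str, Sequence[str]] | None = None,
    lfc_threshold: float = 2.0,
    alpha: float = 0.05,
    accumulate_terms: Sequence[str] | None = None,
) -> MrnaWorkflowResult:
    """Ortholog-matrix comparison of the focal species against every other.

    Genes expressed in no library are excluded; TMM factors are computed for
    the normalized expression analyses; DE is tested per species pair with
    the NB model and called at |log2FC| > ``lfc_threshold`` and BH-adjusted
    p < ``alpha``; calls are intersected and the common up/down sets are GO
    enrichment tested (when a map is supplied).
    """
    expressed = filter_expressed(matrix)
    factors = tmm_factors(expressed)
    x = expressed.counts
    lib_sizes = x.sum(axis=0)
    effective = lib_sizes * factors
    normalized = x / effective * float(np.exp(np.mean(np.log(effective))))
    species_of = expressed.species
    others = sorted(set(species_of.values()) - {focal_species})
    if not others:
        raise ValueError("need at least one non-focal species")
    de_tables = {}
    calls = {}
    for sp in others:
        libs_other = expressed.libraries_of(sp)
        libs_focal = expressed.libraries_of(focal_species)
        res = nb_de_test(
            x, group_a=libs_other, group_b=libs_focal,
            lfc_threshold=lfc_threshold, alpha=alpha,
        )
        de_tables[f"{focal_species}_vs_{sp}"] = res.table
        calls[sp] = res.calls()
    if len(calls) >= 2:
        common_up, common_down = intersect_de(calls)
    else:
        only = next(iter(calls.values()))
        common_up = {f for f, c in only.items() if c == "up"}
        common_down = {f for f, c in only.items() if c == "down"}
    enrichment_up = enrichment_down = accumulated = None
    if go_map is not None:
        from .targets import fisher_go_enrichment

        background = set(x.index)
        if common_up:
            enrichment_up = fisher_go_enrichment(common_up, background, go_map)
        if common_down:
            enrichment_down = fisher_go_enrichment(common_down, background, go_map)
        if accumulate_terms is None:
            terms = []
            for table in (enrichment_up, enrichment_down):
                if table is not None:
                    terms.extend(table.loc[table["fdr"] < 0.05, "term"].tolist())
            accumulate_terms = sorted(set(terms))
        if accumulate_terms:
            accumulated = accumulate_go_expression(
                expressed.with_counts(normalized), go_map, accumulate_terms
            )
    return MrnaWorkflowResult(
        de_tables=de_tables,
        common_up=common_up,
        common_down=common_down,
        enrichment_up=enrichment_up,
        enrichment_down=enrichment_down,
        accumulated=accumulated,
        tmm=factors,
    )


__all__ = [
    "MrnaWorkflowResult",
    "RunConfig",
    "StageError",
    "WorkflowResult",
    "run_mirnome_workflow",
    "run_mrna_workflow",
]
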