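"""Synthetic data with the statistical structure the pipeline assumes.

One seeded configuration generates every input the analysis consumes:

* adapter-ligated small-RNA reads with Phred qualities for each library,
  including reads designed to fail each QC filter;
* mature and precursor sequences for conserved miRNA families (paralogs
  mutated outside the seed region) and for species-specific miRNA;
* toy genomes with gene annotations, into which precursors are planted at
  controlled Hamming distances and genomic locus classes;
* a negative-binomial mRNA count matrix over 1:1 orthologs with planted
  species-level fold changes, a gene->GO map with one enriched term, and
  3'-UTR sequences.

Alongside each output a truth table records the planted structure, so every
pipeline stage can be scored against a known answer.  A fixed config + seed
yields byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomics import Feature, GeneAnnotation
from .preprocess import Read
from .records import CountMatrix, MatureRecord, extract_seed, reverse_complement

_BASES = "ACGT"

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGGAACTCCAA"


@dataclass(frozen=True)
class SimConfig:
    """Seeded configuration of the whole synthetic study.

    The defaults describe a desk-scale version of a four-species blood
    miRNome comparison: conserved miRNA families shared by all species with
    up to two non-seed substitutions between paralogs, species-specific
    miRNA confined to one species, 50-bp reads carrying the standard small
    RNA 3' adapter, and NB2 counts (Var = mu + alpha*mu^2).
    """

    seed: int = 0
    n_species: int = 4
    libraries_per_species: int = 3
    n_conserved_families: int = 37
    n_specific_per_species: int = 20
    paralogs_per_family: int = 2
    mature_len_range: tuple[int, int] = (20, 24)
    adapter: str = DEFAULT_ADAPTER
    read_len: int = 50
    nb_mean_range: tuple[float, float] = (20.0, 200.0)
    nb_dispersion: float = 0.05
    de_fraction: float = 0.1
    de_log2fc: float = 4.0
    genome_len: int = 60_000
    plant_mismatches_specific: int = 5
    plant_mismatches_shared: int = 1
    # auxiliary knobs (read realism, mRNA side)
    loop_len: int = 15
    low_quality_read_fraction: float = 0.10
    n_base_read_fraction: float = 0.02
    junk_read_fraction: float = 0.05
    high_q: int = 38
    low_q: int = 20
    n_genes: int = 500
    n_go_terms: int = 20
    utr_len_range: tuple[int, int] = (30, 80)
    short_utr_fraction: float = 0.1

    def __post_init__(self) -> None:
        counts = {
            "n_species": self.n_species,
            "libraries_per_species": self.libraries_per_species,
            "n_conserved_families": self.n_conserved_families,
            "paralogs_per_family": self.paralogs_per_family,
            "read_len": self.read_len,
            "genome_len": self.genome_len,
            "n_genes": self.n_genes,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.n_specific_per_species < 0:
            raise ValueError("n_specific_per_species must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not (self.plant_mismatches_specific > 3 >= self.plant_mismatches_shared):
            raise ValueError(
                "need plant_mismatches_specific > 3 >= plant_mismatches_shared"
            )
        if self.plant_mismatches_shared < 0:
            raise ValueError("plant_mismatches_shared must be >= 0")
        lo, hi = self.mature_len_range
        if not (7 <= lo <= hi):
            raise ValueError("mature_len_range must satisfy 7 <= lo <= hi")
        # a trimmable read needs the full insert plus >= 5 nt of adapter
        if hi + 5 > self.read_len:
            raise ValueError(
                "mature_len_range exceeds read_len after adapter ligation: "
                f"need max mature ({hi}) + 5 <= read_len ({self.read_len})"
            )
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        if not self.adapter:
            raise ValueError("adapter must be non-empty")

    @property
    def species(self) -> list[str]:
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]

    @property
    def libraries(self) -> list[str]:
        return [
            f"{sp}_L{j + 1}"
            for sp in self.species
            for j in range(self.libraries_per_species)
        ]

    @property
    def library_species(self) -> dict[str, str]:
        return {lib: lib.split("_")[0] for lib in self.libraries}

    @property
    def focal_species(self) -> str:
        """The species carrying the planted expression effects."""
        return self.species[0]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _mutate(
    rng: np.random.Generator, seq: str, positions: Sequence[int]
) -> str:
    """Substitute each given position with a different base."""
    chars = list(seq)
    for pos in positions:
        alternatives = [b for b in _BASES if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def _nb_draw(
    rng: np.random.Generator, mean, dispersion: float, size=None
) -> np.ndarray:
    """NB2 sampling: Var = mu + alpha*mu^2 via the gamma-Poisson mixture."""
    r = 1.0 / dispersion
    mean = np.asarray(mean, dtype=float)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _phred_string(quals: Sequence[int]) -> str:
    return "".join(chr(q + 33) for q in quals)


# ---------------------------------------------------------------------------
# miRNome simulation
# ---------------------------------------------------------------------------

@dataclass
class MirnomeBundle:
    """All miRNome-side synthetic inputs plus their truth tables."""

    config: SimConfig
    reads: dict[str, list[Read]]                    # library -> reads
    matures: dict[str, list[MatureRecord]]          # library -> records
    precursors: dict[str, dict[str, str]]           # species -> id -> seq
    shared_precursors: dict[str, str]               # family -> canonical seq
    mature_truth: pd.DataFrame
    family_truth: pd.DataFrame
    counts_truth: pd.DataFrame                      # mirna x library (pre-QC)
    read_truth: dict[str, pd.DataFrame]             # library -> per-read table

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for lib in sorted(self.reads):
            with open(outdir / f"{lib}.fastq", "w") as fh:
                for r in self.reads[lib]:
                    fh.write(f"@{r.id}\n{r.sequence}\n+\n{_phred_string(r.qualities)}\n")
            with open(outdir / f"{lib}.mature.fa", "w") as fh:
                for rec in self.matures[lib]:
                    fh.write(f">{rec.id}_x{rec.count}\n{rec.sequence}\n")
        for species in sorted(self.precursors):
            with open(outdir / f"{species}.precursor.fa", "w") as fh:
                for pid in sorted(self.precursors[species]):
                    fh.write(f">{pid}\n{self.precursors[species][pid]}\n")
        self.mature_truth.to_csv(outdir / "truth_mature.tsv", sep="\t", index=False)
        self.family_truth.to_csv(outdir / "truth_family.tsv", sep="\t", index=False)
        self.counts_truth.to_csv(outdir / "truth_counts.tsv", sep="\t")
        for lib in sorted(self.read_truth):
            self.read_truth[lib].to_csv(
                outdir / f"truth_reads_{lib}.tsv", sep="\t", index=False
            )


def _build_precursor(mature: str, loop: str) -> str:
    """Hairpin-like precursor: mature + loop + star strand.

    The star is the reverse complement of the mature with a 2-nt 3' offset,
    a minimal stand-in for the true hairpin arm (no folding is modelled).
    """
    star = reverse_complement(mature)[2:]
    return mature + loop + star


def simulate_mirnome(config: SimConfig) -> MirnomeBundle:
    """Generate per-library FASTQ, mature/precursor FASTA and truth tables."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.mature_len_range

    # --- conserved families -------------------------------------------------
    used_seeds: set[str] = set()
    families = []
    n_de = int(round(config.de_fraction * config.n_conserved_families))
    de_flags = np.zeros(config.n_conserved_families, dtype=bool)
    de_flags[: n_de] = True
    de_flags = de_flags[rng.permutation(config.n_conserved_families)]
    for f in range(config.n_conserved_families):
        length = int(rng.integers(lo, hi + 1))
        while True:
            base = _random_seq(rng, length)
            seed6 = base[1:7]
            if seed6 not in used_seeds:
                used_seeds.add(seed6)
                break
        non_seed = [0] + list(range(7, length))
        mutable = sorted(rng.choice(non_seed, size=2, replace=False).tolist())
        loop = _random_seq(rng, config.loop_len)
        mu = float(np.exp(rng.uniform(*np.log(config.nb_mean_range))))
        families.append(
            {
                "family": f"fam{f + 1:04d}",
                "base": base,
                "mutable": mutable,
                "loop": loop,
                "mu": mu,
                "de": bool(de_flags[f]),
            }
        )

    # per-species paralog variants; the canonical (first) paralog stays
    # within 1 substitution of the family base so precursors of different
    # species remain within the cross-genome mismatch budget
    mature_rows = []
    precursors: dict[str, dict[str, str]] = {sp: {} for sp in config.species}
    shared_precursors: dict[str, str] = {}
    per_species_variants: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for fam in families:
        shared_precursors[fam["family"]] = _build_precursor(fam["base"], fam["loop"])
        for sp in config.species:
            variants: list[tuple[str, str]] = []
            seen = {fam["base"]} if config.paralogs_per_family > 1 else set()
            # canonical paralog: at most 1 substitution from the base
            k = int(rng.integers(0, 2))
            canon = (
                _mutate(rng, fam["base"], [fam["mutable"][int(rng.integers(0, 2))]])
                if k
                else fam["base"]
            )
            variants.append((f"{fam['family']}_{sp}_p1", canon))
            seen.add(canon)
            for p in range(1, config.paralogs_per_family):
                for _ in range(20):
                    size = int(rng.integers(0, 3))
                    pos = rng.choice(fam["mutable"], size=size, replace=False)
                    var = _mutate(rng, fam["base"], pos.tolist())
                    if var not in seen:
                        break
                seen.add(var)
                variants.append((f"{fam['family']}_{sp}_p{p + 1}", var))
            per_species_variants[(fam["family"], sp)] = variants
            precursors[sp][f"{fam['family']}_{sp}"] = _build_precursor(
                variants[0][1], fam["loop"]
            )
            for mid, seq in variants:
                mature_rows.append(
                    {
                        "mirna_id": mid,
                        "family": fam["family"],
                        "species": sp,
                        "sequence": seq,
                        "seed": extract_seed(seq),
                        "kind": "conserved",
                        "de": fam["de"],
                        "mu": fam["mu"],
                    }
                )

    # --- species-specific miRNA ---------------------------------------------
    specific_rows = []
    for sp in config.species:
        for i in range(config.n_specific_per_species):
            length = int(rng.integers(lo, hi + 1))
            while True:
                seq = _random_seq(rng, length)
                if seq[1:7] not in used_seeds:
                    used_seeds.add(seq[1:7])
                    break
            loop = _random_seq(rng, config.loop_len)
            mu = float(np.exp(rng.uniform(*np.log(config.nb_mean_range))))
            mid = f"spec_{sp}_{i + 1:03d}"
            precursors[sp][mid] = _build_precursor(seq, loop)
            row = {
                "mirna_id": mid,
                "family": mid,
                "species": sp,
                "sequence": seq,
                "seed": extract_seed(seq),
                "kind": "specific",
                "de": False,
                "mu": mu,
            }
            mature_rows.append(row)
            specific_rows.append(row)

    mature_truth = pd.DataFrame(mature_rows)

    # --- per-library counts (NB2) -------------------------------------------
    lib_species = config.library_species
    mirna_order = mature_truth["mirna_id"].tolist()
    mu_by_id = dict(zip(mature_truth["mirna_id"], mature_truth["mu"]))
    counts = pd.DataFrame(0, index=mirna_order, columns=config.libraries, dtype=int)
    fold = 2.0 ** config.de_log2fc
    for lib in config.libraries:
        sp = lib_species[lib]
        for _, row in mature_truth.iterrows():
            if row["species"] != sp:
                continue
            mu = mu_by_id[row["mirna_id"]]
            if row["de"] and sp == config.focal_species:
                mu = mu * fold
            counts.loc[row["mirna_id"], lib] = int(
                _nb_draw(rng, mu, config.nb_dispersion)
            )

    # --- reads ----------------------------------------------------------------
    reads: dict[str, list[Read]] = {}
    matures: dict[str, list[MatureRecord]] = {}
    read_truth: dict[str, pd.DataFrame] = {}
    seq_by_id = dict(zip(mature_truth["mirna_id"], mature_truth["sequence"]))
    for lib in config.libraries:
        lib_reads: list[Read] = []
        truth_rows: list[dict] = []
        present = counts.loc[counts[lib] > 0, lib]
        recs = [
            MatureRecord(id=mid, sequence=seq_by_id[mid], library=lib, count=int(c))
            for mid, c in present.items()
        ]
        matures[lib] = recs
        for rec in recs:
            for _ in range(rec.count):
                read = _assemble_read(rng, config, lib, len(lib_reads), rec.sequence)
                _append_truth(truth_rows, read, rec.id, rec.sequence, True)
                lib_reads.append(read)
        # junk reads exercising the length filter: no-adapter reads and
        # short/long inserts
        n_junk = int(round(config.junk_read_fraction * len(lib_reads)))
        for _ in range(n_junk):
            mode = ("no_adapter", "short", "long")[int(rng.integers(0, 3))]
            if mode == "no_adapter":
                insert = _random_seq(rng, config.read_len)
                read = _assemble_read(rng, config, lib, len(lib_reads), insert,
                                      ligate=False)
            elif mode == "short":
                insert = _random_seq(rng, int(rng.integers(8, 18)))
                read = _assemble_read(rng, config, lib, len(lib_reads), insert)
            else:
                max_long = min(35, config.read_len - 5)
                insert = _random_seq(rng, int(rng.integers(26, max_long + 1)))
                read = _assemble_read(rng, config, lib, len(lib_reads), insert)
            _append_truth(truth_rows, read, "junk", insert, mode != "no_adapter")
            lib_reads.append(read)
        reads[lib] = lib_reads
        read_truth[lib] = pd.DataFrame(truth_rows)

    family_truth = pd.DataFrame(
        [
            {
                "family": fam["family"],
                "seed": extract_seed(fam["base"]),
                "mu": fam["mu"],
                "de": fam["de"],
                "de_species": config.focal_species if fam["de"] else "",
                "de_log2fc": config.de_log2fc if fam["de"] else 0.0,
            }
            for fam in families
        ]
    )

    return MirnomeBundle(
        config=config,
        reads=reads,
        matures=matures,
        precursors=precursors,
        shared_precursors=shared_precursors,
        mature_truth=mature_truth,
        family_truth=family_truth,
        counts_truth=counts,
        read_truth=read_truth,
    )


def _assemble_read(
    rng: np.random.Generator,
    config: SimConfig,
    lib: str,
    index: int,
    insert: str,
    ligate: bool = True,
) -> Read:
    """Insert + 3' adapter padded/truncated to read_len, with qualities."""
    seq = insert + (config.adapter if ligate else "")
    if len(seq) < config.read_len:
        seq = seq + _random_seq(rng, config.read_len - len(seq))
    seq = seq[: config.read_len]
    bad = rng.random() < config.low_quality_read_fraction
    p_high = 0.5 if bad else 0.95
    high = rng.random(len(seq)) < p_high
    quals = tuple(np.where(high, config.high_q, config.low_q).tolist())
    if rng.random() < config.n_base_read_fraction and insert:
        pos = int(rng.integers(0, min(len(insert), len(seq))))
        seq = seq[:pos] + "N" + seq[pos + 1:]
    return Read(id=f"{lib}_r{index + 1:06d}", sequence=seq, qualities=quals)


def _append_truth(truth_rows: list[dict], read: Read, origin: str, insert: str,
                  has_adapter: bool) -> None:
    has_n = "N" in read.sequence
    # record the read's actual insert bases (an N may have been planted) and
    # the high-quality fraction over that trimmed portion
    insert = read.sequence[: len(insert)]
    k = max(len(insert), 1)
    frac_q30 = sum(1 for q in read.qualities[:k] if q >= 30) / k
    truth_rows.append(
        {
            "read_id": read.id,
            "origin": origin,
            "insert": insert,
            "insert_len": len(insert),
            "has_adapter": has_adapter,
            "has_n": has_n,
            "frac_q30": frac_q30,
        }
    )


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

_LOCUS_CYCLE = ("intergenic", "exonic", "intronic", "exon_intron_boundary")


@dataclass
class GenomeBundle:
    """Per-species toy genomes, annotations and the planting truth."""

    config: SimConfig
    genomes: dict[str, dict[str, str]]           # species -> chrom -> seq
    annotations: dict[str, GeneAnnotation]
    plant_truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp in sorted(self.genomes):
            with open(outdir / f"{sp}.genome.fa", "w") as fh:
                for chrom in sorted(self.genomes[sp]):
                    fh.write(f">{chrom}\n")
                    seq = self.genomes[sp][chrom]
                    for i in range(0, len(seq), 80):
                        fh.write(seq[i : i + 80] + "\n")
            with open(outdir / f"{sp}.exons.bed", "w") as fh:
                for e in self.annotations[sp].exons:
                    fh.write(
                        f"{e.chrom}\t{e.start}\t{e.end}\t{e.gene}\t0\t{e.strand}\n"
                    )
        self.plant_truth.to_csv(outdir / "truth_plants.tsv", sep="\t", index=False)


def _place_genes(
    rng: np.random.Generator, chrom: str, genome_len: int, n_genes: int = 5
) -> list[Feature]:
    """Non-overlapping genes of 3 exons (300 nt) / 2 introns (200 nt)."""
    exon_len, intron_len = 300, 200
    span = 3 * exon_len + 2 * intron_len
    exons: list[Feature] = []
    occupied: list[tuple[int, int]] = []
    attempts = 0
    placed = 0
    while placed < n_genes and attempts < 200 * n_genes:
        attempts += 1
        start = int(rng.integers(0, max(genome_len - span, 1)))
        if any(s < start + span + 100 and start < e + 100 for s, e in occupied):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        gene = f"{chrom}_g{placed + 1}"
        pos = start
        for _ in range(3):
            exons.append(Feature(chrom, pos, pos + exon_len, gene, strand))
            pos += exon_len + intron_len
        occupied.append((start, start + span))
        placed += 1
    if placed < n_genes:
        raise ValueError("genome_len too small to place the gene annotation")
    return exons


def _free_position(
    rng: np.random.Generator,
    candidates: list[int],
    length: int,
    occupied: list[tuple[int, int]],
    margin: int = 10,
) -> int | None:
    order = rng.permutation(len(candidates))
    for idx in order[: min(len(order), 200)]:
        start = candidates[idx]
        end = start + length
        if all(e + margin <= start or end + margin <= s for s, e in occupied):
            return start
    return None


def simulate_genomes(
    config: SimConfig,
    shared_precursors: Mapping[str, str],
    specific_precursors: Mapping[str, Mapping[str, str]],
) -> GenomeBundle:
    """Toy genomes with precursors planted at controlled distances.

    Shared precursors are planted into every genome within
    ``plant_mismatches_shared`` substitutions; species-specific precursors
    into their own genome within the shared budget, and into foreign genomes
    either not at all or at exactly ``plant_mismatches_specific + 1``
    substitutions.  Plant locations cycle through intergenic / exonic /
    intronic / boundary loci so the locus classifier can be scored.
    """
    if not shared_precursors and not all(specific_precursors.values()):
        raise ValueError("no precursors to plant")
    rng = np.random.default_rng(config.seed + 1)
    genomes: dict[str, dict[str, str]] = {}
    annotations: dict[str, GeneAnnotation] = {}
    rows = []
    for sp in config.species:
        chrom = f"{sp}_chr1"
        genome = np.frombuffer(
            _random_seq(rng, config.genome_len).encode("ascii"), dtype=np.uint8
        ).copy()
        n_classified = len(shared_precursors) + len(specific_precursors.get(sp, {}))
        n_genes = max(5, -(-n_classified // 8))  # enough junctions for plants
        exons = _place_genes(rng, chrom, config.genome_len, n_genes)
        annotation = GeneAnnotation.from_exons(exons)
        occupied: list[tuple[int, int]] = []  # plants only; genes may host them
        plants: list[tuple[str, str, int, str, bool]] = []
        for fam in sorted(shared_precursors):
            d = int(rng.integers(0, config.plant_mismatches_shared + 1))
            plants.append((fam, shared_precursors[fam], d, "shared", True))
        for pid in sorted(specific_precursors.get(sp, {})):
            d = int(rng.integers(0, config.plant_mismatches_shared + 1))
            plants.append((pid, specific_precursors[sp][pid], d, "specific_own", True))
        foreign_toggle = 0
        for other in config.species:
            if other == sp:
                continue
            for pid in sorted(specific_precursors.get(other, {})):
                if foreign_toggle % 2 == 0:
                    d = config.plant_mismatches_specific + 1
                    plants.append(
                        (pid, specific_precursors[other][pid], d,
                         "specific_foreign", False)
                    )
                else:
                    rows.append(
                        {
                            "precursor": pid,
                            "genome_species": sp,
                            "chrom": chrom,
                            "start": -1,
                            "end": -1,
                            "strand": ".",
                            "mismatches": -1,
                            "role": "specific_absent",
                            "locus_class": "",
                        }
                    )
                foreign_toggle += 1
        targeted = [
            (pid, seq, d, role, _LOCUS_CYCLE[k % 4] if classify else "intergenic",
             classify)
            for k, (pid, seq, d, role, classify) in enumerate(plants)
        ]
        # place the scarcest locus classes first so exonic/intronic plants
        # cannot crowd out the few exon/intron junctions
        order = {"exon_intron_boundary": 0, "intronic": 1, "exonic": 2,
                 "intergenic": 3}
        targeted.sort(key=lambda t: order[t[4]])
        for pid, seq, d, role, target, classify in targeted:
            length = len(seq)
            placement = _plant_position(rng, target, length, annotation, occupied,
                                        config.genome_len)
            if placement is None:
                raise ValueError("genome_len too small to host all plants")
            start, strand = placement
            if strand is None:  # intergenic: strand unconstrained
                strand = "+" if rng.random() < 0.5 else "-"
            positions = rng.choice(length, size=d, replace=False) if d else []
            mutated = _mutate(rng, seq, sorted(int(p) for p in positions))
            planted = mutated if strand == "+" else reverse_complement(mutated)
            genome[start : start + length] = np.frombuffer(
                planted.encode("ascii"), dtype=np.uint8
            )
            occupied.append((start, start + length))
            rows.append(
                {
                    "precursor": pid,
                    "genome_species": sp,
                    "chrom": chrom,
                    "start": start,
                    "end": start + length,
                    "strand": strand,
                    "mismatches": d,
                    "role": role,
                    "locus_class": target if classify else "",
                }
            )
        genomes[sp] = {chrom: genome.tobytes().decode("ascii")}
        annotations[sp] = annotation
    return GenomeBundle(
        config=config,
        genomes=genomes,
        annotations=annotations,
        plant_truth=pd.DataFrame(rows),
    )


def _plant_position(
    rng: np.random.Generator,
    target: str,
    length: int,
    annotation: GeneAnnotation,
    occupied: list[tuple[int, int]],
    genome_len: int,
) -> tuple[int, str | None] | None:
    """Pick a free start for a plant in the requested locus class.

    Genic targets inherit the host gene's strand (miRNA genes are
    strand-specific); intergenic plants return strand ``None``.
    """
    margin = 5
    candidates: list[tuple[int, str | None]]
    if target == "exonic":
        candidates = [
            (int(p), e.strand)
            for e in annotation.exons
            if e.end - e.start >= length + 2 * margin
            for p in range(e.start + margin, e.end - length - margin)
        ]
    elif target == "intronic":
        candidates = [
            (int(p), i.strand)
            for i in annotation.introns
            if i.end - i.start >= length + 2 * margin
            for p in range(i.start + margin, i.end - length - margin)
        ]
    elif target == "exon_intron_boundary":
        candidates = []
        for i in annotation.introns:
            # junctions at both intron ends; centre the plant on the junction
            for junction in (i.start, i.end):
                start = junction - length // 2
                if 0 <= start and start + length <= genome_len:
                    candidates.append((start, i.strand))
    else:  # intergenic
        gene_spans: dict[str, tuple[int, int]] = {}
        for e in annotation.exons:
            s, t = gene_spans.get(e.gene, (e.start, e.end))
            gene_spans[e.gene] = (min(s, e.start), max(t, e.end))
        spans = sorted(gene_spans.values())
        candidates = []
        prev = 0
        for s, t in spans + [(genome_len, genome_len)]:
            if s - prev >= length + 2 * margin:
                step = max((s - prev) // 50, 1)
                candidates.extend(
                    (int(p), None) for p in range(prev + margin, s - length - margin, step)
                )
            prev = max(prev, t)
    if not candidates:
        return None
    starts = [c[0] for c in candidates]
    start = _free_position(rng, starts, length, occupied)
    if start is None:
        return None
    return start, candidates[starts.index(start)][1]


# ---------------------------------------------------------------------------
# mRNA simulation
# ---------------------------------------------------------------------------

@dataclass
class MrnaBundle:
    """Ortholog count matrix, GO map, UTRs and their truth tables."""

    config: SimConfig
    counts: CountMatrix
    ortholog_table: pd.DataFrame
    go_map: dict[str, list[str]]
    enriched_term: str
    utrs: dict[str, str]
    gene_truth: pd.DataFrame
    size_factor_truth: pd.Series

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.counts.to_csv(outdir / "mrna_counts.tsv", sep="\t")
        self.ortholog_table.to_csv(outdir / "orthologs.tsv", sep="\t", index=False)
        with open(outdir / "go_map.tsv", "w") as fh:
            for gene in sorted(self.go_map):
                for term in self.go_map[gene]:
                    fh.write(f"{gene}\t{term}\n")
        with open(outdir / "utrs.fa", "w") as fh:
            for gene in sorted(self.utrs):
                fh.write(f">{gene}\n{self.utrs[gene]}\n")
        self.gene_truth.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        self.size_factor_truth.to_csv(outdir / "truth_size_factors.tsv", sep="\t")


def simulate_mrna_counts(
    config: SimConfig,
    size_factors: Mapping[str, float] | None = None,
) -> MrnaBundle:
    """NB2 ortholog counts with planted species effects, GO map and UTRs.

    Planted DE genes shift their mean by 2^de_log2fc in the focal species
    (alternating up/down); one GO term is enriched among the planted genes
    by construction (it annotates at least 80 % of them).
    """
    rng = np.random.default_rng(config.seed + 2)
    genes = [f"gene{i + 1:05d}" for i in range(config.n_genes)]
    libraries = config.libraries
    if size_factors is None:
        sf = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(libraries)))
    else:
        sf = np.array([size_factors[lib] for lib in libraries], dtype=float)
    size_factor_truth = pd.Series(sf, index=libraries, name="size_factor")

    mu = np.exp(rng.uniform(*np.log(config.nb_mean_range), size=config.n_genes))
    n_de = int(round(config.de_fraction * config.n_genes))
    de_idx = rng.permutation(config.n_genes)[:n_de]
    direction = np.zeros(config.n_genes, dtype=int)
    direction[de_idx] = np.where(np.arange(n_de) % 2 == 0, 1, -1)

    fold = 2.0 ** config.de_log2fc
    lib_species = config.library_species
    matrix = np.zeros((config.n_genes, len(libraries)), dtype=int)
    for j, lib in enumerate(libraries):
        mu_l = mu.copy()
        if lib_species[lib] == config.focal_species:
            mu_l = mu_l * np.where(direction == 1, fold, 1.0)
            mu_l = mu_l * np.where(direction == -1, 1.0 / fold, 1.0)
        matrix[:, j] = _nb_draw(rng, mu_l * sf[j], config.nb_dispersion)

    counts = CountMatrix(
        counts=pd.DataFrame(matrix, index=genes, columns=libraries),
        species=lib_species,
    )

    # gene -> GO terms; terms[0] is the designed enriched term
    terms = [f"GO:{i + 1:07d}" for i in range(config.n_go_terms)]
    enriched = terms[0]
    go_map: dict[str, list[str]] = {}
    background_terms = terms[1:]
    for i, gene in enumerate(genes):
        k = int(rng.integers(1, 4))
        chosen = rng.choice(len(background_terms), size=k, replace=False)
        go_map[gene] = sorted(background_terms[c] for c in chosen)
    de_genes = [genes[i] for i in sorted(de_idx)]
    annotated = [g for g in de_genes if rng.random() < 0.9]
    # construction guarantee: the enriched term covers >= 80 % of DE genes
    while len(annotated) < math.ceil(0.8 * len(de_genes)):
        remaining = [g for g in de_genes if g not in annotated]
        annotated.append(remaining[0])
    for gene in annotated:
        go_map[gene] = sorted(go_map[gene] + [enriched])
    for gene in genes:
        if gene not in de_genes and rng.random() < 0.02:
            go_map[gene] = sorted(go_map[gene] + [enriched])

    utr_lo, utr_hi = config.utr_len_range
    utrs = {}
    for gene in genes:
        if rng.random() < config.short_utr_fraction:
            length = int(rng.integers(5, 20))
        else:
            length = int(rng.integers(utr_lo, utr_hi + 1))
        utrs[gene] = _random_seq(rng, length)

    ortholog_table = pd.DataFrame(
        {
            "ortholog_id": genes,
            **{sp: [f"{g}_{sp}" for g in genes] for sp in config.species},
        }
    )
    gene_truth = pd.DataFrame(
        {
            "gene": genes,
            "mu": mu,
            "de": direction != 0,
            "direction": np.where(
                direction == 1, "up", np.where(direction == -1, "down", "")
            ),
            "enriched_term_member": [g in set(annotated) for g in genes],
        }
    )
    return MrnaBundle(
        config=config,
        counts=counts,
        ortholog_table=ortholog_table,
        go_map=go_map,
        enriched_term=enriched,
        utrs=utrs,
        gene_truth=gene_truth,
        size_factor_truth=size_factor_truth,
    )


__all__ = [
    "DEFAULT_ADAPTER",
    "GenomeBundle",
    "MirnomeBundle",
    "MrnaBundle",
    "SimConfig",
    "simulate_genomes",
    "simulate_mirnome",
    "simulate_mrna_counts",
]
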