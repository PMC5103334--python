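import hashlib
from pathlib import Path

import numpy as np
import pytest

from mirnome.records import reverse_complement
from mirnome.synthdata import (
    SimConfig,
    simulate_genomes,
    simulate_mirnome,
    simulate_mrna_counts,
)


def tree_digest(directory: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(directory.rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestSimConfigValidation:
    def test_defaults_are_valid(self):
        SimConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_species": 0},
            {"nb_dispersion": 0.0},
            {"plant_mismatches_specific": 3},
            {"plant_mismatches_shared": 4, "plant_mismatches_specific": 5},
            {"mature_len_range": (20, 48)},  # insert + adapter will not fit
            {"de_fraction": 1.5},
            {"adapter": ""},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestSimulateMirnome:
    def test_no_specific_mirna_when_disabled(self):
        cfg = SimConfig(seed=2, n_conserved_families=4, n_specific_per_species=0)
        bundle = simulate_mirnome(cfg)
        assert (bundle.mature_truth["kind"] == "specific").sum() == 0

    def test_de_fraction_flags_exact_family_count(self):
        cfg = SimConfig(seed=2, n_conserved_families=100, de_fraction=0.2,
                        n_specific_per_species=0, libraries_per_species=1)
        bundle = simulate_mirnome(cfg)
        assert int(bundle.family_truth["de"].sum()) == 20

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        cfg = SimConfig(seed=9, n_conserved_families=4, n_specific_per_species=2)
        digests = []
        for run in ("r1", "r2"):
            out = tmp_path / run
            simulate_mirnome(cfg).write(out)
            digests.append(tree_digest(out))
        assert digests[0] == digests[1]

    def test_conserved_families_span_all_species(self, small_config, mirnome_bundle):
        truth = mirnome_bundle.mature_truth
        conserved = truth[truth.kind == "conserved"]
        for fam, sub in conserved.groupby("family"):
            assert set(sub["species"]) == set(small_config.species)
            assert sub["seed"].nunique() == 1  # seed region is untouched

    def test_specific_mirna_confined_to_one_species(self, mirnome_bundle):
        truth = mirnome_bundle.mature_truth
        specific = truth[truth.kind == "specific"]
        assert (specific.groupby("mirna_id")["species"].nunique() == 1).all()

    def test_paralogs_stay_within_two_substitutions_of_base(
        self, small_config, mirnome_bundle
    ):
        truth = mirnome_bundle.mature_truth
        conserved = truth[truth.kind == "conserved"]
        for fam, sub in conserved.groupby("family"):
            seqs = sub["sequence"].tolist()
            for seq in seqs:
                for other in seqs:
                    assert len(seq) == len(other)
                    d = sum(a != b for a, b in zip(seq, other))
                    assert d <= 2

    def test_precursor_embeds_mature_loop_and_star(self, small_config, mirnome_bundle):
        sp = small_config.species[0]
        truth = mirnome_bundle.mature_truth
        for pid, pre in list(mirnome_bundle.precursors[sp].items())[:5]:
            if pid.startswith("spec_"):
                mature = truth.loc[truth.mirna_id == pid, "sequence"].iloc[0]
            else:
                mature = truth.loc[truth.mirna_id == f"{pid}_p1", "sequence"].iloc[0]
            assert pre.startswith(mature)
            assert pre.endswith(reverse_complement(mature)[2:])
            assert len(pre) == 2 * len(mature) + small_config.loop_len - 2

    def test_reads_are_insert_plus_adapter_at_read_length(
        self, small_config, mirnome_bundle
    ):
        lib = small_config.libraries[0]
        truth = mirnome_bundle.read_truth[lib].set_index("read_id")
        for read in mirnome_bundle.reads[lib][:100]:
            row = truth.loc[read.id]
            assert len(read.sequence) == small_config.read_len
            assert len(read.qualities) == small_config.read_len
            if row["has_adapter"] and not row["has_n"]:
                k = row["insert_len"]
                tail = read.sequence[k : k + 5]
                assert tail == small_config.adapter[:5]

    def test_every_read_has_exactly_one_truth_row(self, mirnome_bundle):
        for lib, reads in mirnome_bundle.reads.items():
            truth = mirnome_bundle.read_truth[lib]
            assert truth["read_id"].is_unique
            assert {r.id for r in reads} == set(truth["read_id"])

    def test_counts_truth_covers_exactly_the_emitted_records(self, mirnome_bundle):
        truth = mirnome_bundle.counts_truth
        for lib, recs in mirnome_bundle.matures.items():
            expected = truth.loc[truth[lib] > 0, lib]
            assert {r.id: r.count for r in recs} == dict(expected)

    def test_overlong_inserts_rejected_by_config(self):
        with pytest.raises(ValueError):
            SimConfig(read_len=20, mature_len_range=(20, 24))


class TestSimulateGenomes:
    def test_verbatim_plant_has_zero_truth_distance(
        self, genome_bundle, mirnome_bundle
    ):
        truth = genome_bundle.plant_truth
        assert (truth.loc[truth.role == "shared", "mismatches"] >= 0).all()
        assert (truth.loc[truth.role == "shared", "mismatches"] <= 1).all()

    def test_foreign_specific_plants_exceed_the_distance_floor(
        self, small_config, genome_bundle
    ):
        truth = genome_bundle.plant_truth
        foreign = truth[truth.role == "specific_foreign"]
        assert (foreign["mismatches"] > small_config.plant_mismatches_specific).all()

    def test_reextracted_plants_reproduce_recorded_mismatches(
        self, small_config, mirnome_bundle, genome_bundle, specific_precursors
    ):
        allpre = dict(mirnome_bundle.shared_precursors)
        for sp in small_config.species:
            allpre.update(specific_precursors[sp])
        checked = 0
        for row in genome_bundle.plant_truth.itertuples():
            if row.start < 0:
                continue
            seq = genome_bundle.genomes[row.genome_species][row.chrom][
                row.start : row.end
            ]
            if row.strand == "-":
                seq = reverse_complement(seq)
            ref = allpre[row.precursor]
            d = sum(a != b for a, b in zip(seq, ref))
            assert d == row.mismatches
            checked += 1
        assert checked > 20

    def test_too_small_genome_raises(self, mirnome_bundle, specific_precursors):
        cfg = SimConfig(seed=1, genome_len=2600, n_conserved_families=8,
                        n_specific_per_species=4)
        with pytest.raises(ValueError):
            simulate_genomes(cfg, mirnome_bundle.shared_precursors,
                             specific_precursors)


class TestSimulateMrna:
    def test_sample_means_match_planted_means_without_effects(self):
        cfg = SimConfig(seed=31, n_species=4, libraries_per_species=50,
                        n_genes=60, de_log2fc=0.0, de_fraction=0.0)
        bundle = simulate_mrna_counts(
            cfg, size_factors={lib: 1.0 for lib in cfg.libraries}
        )
        x = bundle.counts.counts
        mu = bundle.gene_truth.set_index("gene")["mu"]
        n = x.shape[1]
        failures = 0
        for gene in x.index:
            se = np.sqrt((mu[gene] + cfg.nb_dispersion * mu[gene] ** 2) / n)
            if abs(x.loc[gene].mean() - mu[gene]) > 3 * se:
                failures += 1
        assert failures <= 2  # ~0.3% expected per gene at 3 standard errors

    def test_library_size_factor_scales_column_sums(self):
        cfg = SimConfig(seed=32, n_species=2, libraries_per_species=2,
                        n_genes=800, de_fraction=0.0)
        sf = {lib: 1.0 for lib in cfg.libraries}
        sf[cfg.libraries[1]] = 2.0
        bundle = simulate_mrna_counts(cfg, size_factors=sf)
        sums = bundle.counts.counts.sum(axis=0)
        ratio = sums[cfg.libraries[1]] / sums[cfg.libraries[0]]
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_enriched_term_covers_most_planted_genes(self, mrna_bundle):
        truth = mrna_bundle.gene_truth
        de_genes = set(truth.loc[truth.de, "gene"])
        annotated = {
            g for g in de_genes if mrna_bundle.enriched_term in mrna_bundle.go_map[g]
        }
        assert len(annotated) >= 0.8 * len(de_genes)

    def test_utr_lengths_respect_decoy_fraction(self, mrna_bundle):
        lengths = np.array([len(s) for s in mrna_bundle.utrs.values()])
        assert (lengths >= 20).mean() > 0.8
        assert (lengths < 20).any()

    def test_planted_effects_shift_focal_species_means(self, mrna_bundle):
        truth = mrna_bundle.gene_truth
        cfg = mrna_bundle.config
        x = mrna_bundle.counts.counts
        focal_libs = [l for l in x.columns if cfg.library_species[l] == cfg.focal_species]
        other_libs = [l for l in x.columns if l not in focal_libs]
        up = truth.loc[truth.direction == "up", "gene"]
        ratio = (x.loc[up, focal_libs].mean(axis=1) + 1) / (
            x.loc[up, other_libs].mean(axis=1) + 1
        )
        assert (np.log2(ratio) > 2).mean() > 0.9
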