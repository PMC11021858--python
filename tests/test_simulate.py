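import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from scatdna.config import RunConfig
from scatdna.genotyping import HET, HOM1, HOM2, Panel, genotype_samples
from scatdna.pedigree import trio_incompatibility
from scatdna.simulate import (CATEGORIES, CONTAMINANT_TAXON, SimConfig, GroundTruth,
                              category_map, individual_scenario, island_config,
                              mainland_config, reference_database, simulate_dataset,
                              simulate_diets, simulate_genotype_reads,
                              simulate_genotypes, simulate_pedigree,
                              simulate_scats_and_reads, write_dataset)
from scatdna.taxonomy import classify_all
from scatdna import diet as diet_mod


class TestPedigreeSim:
    def test_no_mortality_population_never_shrinks(self):
        cfg = SimConfig(harvest_prob=0.0, natural_death_prob=0.0, n_years=4)
        ped, alive_years = simulate_pedigree(cfg, seed=3)
        sizes = {}
        for iid, years in alive_years.items():
            for y in years:
                sizes[y] = sizes.get(y, 0) + 1
        values = [sizes[y] for y in sorted(sizes)]
        assert values == sorted(values)

    def test_fixed_litter_arithmetic(self):
        # founder pair + 3 years x 4 pups, no deaths
        cfg = SimConfig(litter_fixed=4, n_years=3, harvest_prob=0.0,
                        natural_death_prob=0.0)
        ped, _ = simulate_pedigree(cfg, seed=0)
        assert len(ped.records) == 2 + 12

    def test_same_seed_identical(self):
        cfg = SimConfig()
        p1, y1 = simulate_pedigree(cfg, seed=11)
        p2, y2 = simulate_pedigree(cfg, seed=11)
        assert p1.records == p2.records and y1 == y2

    def test_distinct_seeds_differ(self):
        cfg = SimConfig()
        p1, _ = simulate_pedigree(cfg, seed=1)
        p2, _ = simulate_pedigree(cfg, seed=2)
        assert p1.records != p2.records

    def test_acyclic_and_parents_sexed(self):
        ped, _ = simulate_pedigree(SimConfig(), seed=7)  # Pedigree() validates
        for rec in ped.records.values():
            if rec.dam_id:
                assert ped.records[rec.dam_id].sex == "F"
            if rec.sire_id:
                assert ped.records[rec.sire_id].sex == "M"


class TestGenotypeSim:
    def test_every_trio_mendelian(self):
        cfg = SimConfig()
        ped, _ = simulate_pedigree(cfg, seed=4)
        genos, _ = simulate_genotypes(ped, cfg, seed=5)
        for iid, rec in ped.records.items():
            if rec.dam_id and rec.sire_id:
                count, _ = trio_incompatibility(
                    genos[iid], genos[rec.dam_id], genos[rec.sire_id])
                assert count == 0

    def test_founder_genotypes_near_hwe(self):
        """Large founder cohort matches Hardy-Weinberg proportions."""
        from scatdna.pedigree import PedigreeRecord, Pedigree
        recs = [PedigreeRecord(f"I{i}", "F") for i in range(500)]
        cfg = SimConfig(n_autosomal_loci=1, founder_freq_low=0.5,
                        founder_freq_high=0.5)
        genos, freqs = simulate_genotypes(Pedigree(recs), cfg, seed=9)
        counts = {HOM1: 0, HET: 0, HOM2: 0}
        for g in genos.values():
            counts[g["snp01"]] += 1
        expected = np.array([0.25, 0.5, 0.25]) * 500
        stat, p = chisquare([counts[HOM1], counts[HET], counts[HOM2]], expected)
        assert p > 0.001


class TestScatSim:
    def test_true_items_recovered_without_contamination(self):
        cfg = island_config(contamination_rate=0.0)
        diets = simulate_diets(["W1", "W2"], cfg, seed=2)
        counts, sheet, truth = simulate_scats_and_reads(
            diets, {"W1": [2016, 2017], "W2": [2016]}, cfg, seed=3)
        cmap = category_map()
        for c in classify_all(counts):
            assert c.status == "wolf_diet"
            items = diet_mod.scat_items(c, cmap)
            assert items == truth[c.sample_id][1]

    def test_high_concentration_shared_mean_overlap_near_one(self):
        cfg = island_config(dirichlet_alpha=1e6)
        diets = simulate_diets([f"W{i}" for i in range(4)], cfg, seed=1)
        profiles = [diet_mod.DietProfile(i, 1, d) for i, d in diets.items()]
        mean, _ = diet_mod.overlap_summary(profiles)
        assert mean == pytest.approx(1.0, abs=1e-3)

    def test_same_seed_identical_tables(self):
        cfg = island_config()
        diets = simulate_diets(["W1"], cfg, seed=5)
        a, _, _ = simulate_scats_and_reads(diets, {"W1": [2016]}, cfg, seed=6)
        b, _, _ = simulate_scats_and_reads(diets, {"W1": [2016]}, cfg, seed=6)
        pd.testing.assert_frame_equal(a, b)

    def test_contamination_trace_and_single_replicate(self):
        cfg = island_config(contamination_rate=1.0)
        diets = simulate_diets(["W1"], cfg, seed=7)
        counts, _, _ = simulate_scats_and_reads(diets, {"W1": [2016, 2017]}, cfg, 8)
        cont = counts[counts["taxon"] == CONTAMINANT_TAXON]
        assert len(cont) > 0
        for sid, sub in counts.groupby("sample_id"):
            c = sub[sub["taxon"] == CONTAMINANT_TAXON]
            assert len(c) <= 1  # at most one replicate
            if not c.empty:
                assert c["count"].sum() < 0.005 * sub["count"].sum()


class TestGenotypeReadSim:
    def test_noise_free_recovery_is_exact(self):
        cfg = SimConfig(dropout_rate=0.0, false_allele_rate=0.0,
                        locus_failure_rate=0.0, n_autosomal_loci=10)
        ped, _ = simulate_pedigree(cfg, seed=1)
        genos, _ = simulate_genotypes(ped, cfg, seed=2)
        sexes = {i: r.sex for i, r in ped.records.items()}
        owner = {f"S{i}": iid for i, iid in enumerate(list(genos)[:5])}
        panel = Panel.default(10)
        counts = simulate_genotype_reads(genos, sexes, owner, cfg, seed=3,
                                         panel=panel)
        for called in genotype_samples(counts, panel):
            assert called.calls == genos[owner[called.sample_id]]
            assert called.sex == sexes[owner[called.sample_id]]
            assert called.species == "wolf"

    def test_dropout_consensus_rate_matches_closed_form(self):
        """P(het consensus) = P(>=2 of 3 replicates het) at dropout eps."""
        eps = 0.3
        cfg = SimConfig(dropout_rate=eps, false_allele_rate=0.0,
                        locus_failure_rate=0.0, n_autosomal_loci=35)
        rng_genos = {f"I{i}": {f"snp{j:02d}": HET for j in range(1, 36)}
                     for i in range(100)}  # 3500 het loci
        sexes = {f"I{i}": "F" for i in range(100)}
        owner = {f"S{i}": f"I{i}" for i in range(100)}
        counts = simulate_genotype_reads(rng_genos, sexes, owner, cfg, seed=4)
        called = genotype_samples(counts, Panel.default(35))
        n_het = sum(1 for g in called for c in g.calls.values() if c == HET)
        n_total = sum(len(g.calls) for g in called)
        p_rep = 1 - eps  # a replicate shows het iff no dropout (depth is ample)
        p_consensus = 3 * p_rep**2 * (1 - p_rep) + p_rep**3
        se = np.sqrt(p_consensus * (1 - p_consensus) / n_total)
        assert abs(n_het / n_total - p_consensus) < 3 * se


class TestDatasetAssembly:
    def test_ground_truth_consistent_with_files(self, tmp_path):
        cfg = island_config(n_years=3)
        truth, tables = simulate_dataset(cfg, seed=6)
        taxa = set(tables["taxon_counts"]["taxon"])
        known = set(category_map()) | {CONTAMINANT_TAXON, "Canis lupus"}
        assert taxa <= known
        for sid, owner in truth.scat_owner.items():
            assert owner in truth.pedigree.records
        sheet_ids = {r.sample_id for r in tables["sample_sheet"]}
        assert sheet_ids == set(truth.scat_owner)
        write_dataset(truth, tables, tmp_path, seed=6)
        for fname in ["taxon_counts.tsv", "allele_counts.tsv", "sample_sheet.tsv",
                      "panel.csv", "category_map.csv", "reference.fasta",
                      "ground_truth/pedigree.csv"]:
            assert (tmp_path / fname).exists(), fname

    def test_reference_database_taxa_are_dissimilar(self):
        from scatdna.taxonomy import compute_identity
        refs = reference_database(seed=0)
        for i, a in enumerate(refs[:4]):
            for b in refs[i + 1:4]:
                assert compute_identity(a.sequence, b.sequence) < 90.0
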