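import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scatdna.config import RunConfig
from scatdna.genotyping import (HET, HOM1, HOM2, MISSING, NOCALL, MultilocusGenotype,
                                Panel, allele_frequencies, assign_sex, call_replicate,
                                consensus, detection_history, filter_snps,
                                genotype_distance, genotype_samples, hwe_exact,
                                match_individuals, pid_expected, pid_locus, pid_sibs,
                                pid_sibs_locus, qc_sample, species_diagnostic)


class TestCallReplicate:
    @pytest.mark.parametrize("n1,n2,expected", [
        (95, 5, HOM1),    # r = 0.95
        (40, 45, HET),    # r = 0.47
        (4, 3, NOCALL),   # depth 7 < 10
        (5, 95, HOM2),
        (20, 80, NOCALL),  # r = 0.2, between hom2 and het bands
        (9, 0, NOCALL),   # depth 9
        (10, 0, HOM1),
    ])
    def test_threshold_rule(self, n1, n2, expected):
        assert call_replicate(n1, n2) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            call_replicate(-1, 5)


class TestConsensus:
    @pytest.mark.parametrize("calls,expected", [
        ((HET, HET, HOM1), HET),
        ((HOM1, HOM1, HOM1), HOM1),
        ((HOM1, HOM1, NOCALL), MISSING),
        ((HET, HET, HET), HET),
        ((HOM2, HOM2, HOM2), HOM2),
        ((HET, HOM1, HOM1), MISSING),
        ((NOCALL, NOCALL, NOCALL), MISSING),
        ((HET, HET), HET),         # two replicates can still call a het
        ((HOM1, HOM1), MISSING),   # but never a homozygote
    ])
    def test_rule(self, calls, expected):
        assert consensus(calls) == expected

    def test_truth_table_exhaustive(self):
        """All 4^3 replicate triples obey het>=2/3, hom=3/3."""
        for triple in itertools.product((HOM1, HET, HOM2, NOCALL), repeat=3):
            expected = MISSING
            if sum(c == HET for c in triple) >= 2:
                expected = HET
            elif all(c == HOM1 for c in triple):
                expected = HOM1
            elif all(c == HOM2 for c in triple):
                expected = HOM2
            assert consensus(triple) == expected, triple


class TestQcSexSpecies:
    def _geno(self, n_missing, n_loci=35):
        calls = {f"l{i}": (MISSING if i < n_missing else HOM1)
                 for i in range(n_loci)}
        return MultilocusGenotype("s", calls, n_autosomal=n_loci)

    @pytest.mark.parametrize("n_missing,passes", [(8, False), (7, True), (0, True)])
    def test_qc_20pct_boundary(self, n_missing, passes):
        assert qc_sample(self._geno(n_missing)) is passes

    @pytest.mark.parametrize("depths,qc,expected", [
        ((50, 60, 0), True, "M"),
        ((0, 0, 0), True, "F"),
        ((12, 0, 0), True, "unknown"),   # single replicate insufficient
        ((0, 0, 0), False, "unknown"),   # no QC pass, no female call
    ])
    def test_sex_rule(self, depths, qc, expected):
        assert assign_sex(depths, qc) == expected

    def test_species_votes(self):
        panel = Panel.default()
        wolf_calls = {f"diag{i}": HOM1 for i in (1, 2, 3)}
        assert species_diagnostic(wolf_calls, panel) == "wolf"
        coyote_2_missing_1 = {"diag1": HOM2, "diag2": HOM2, "diag3": MISSING}
        assert species_diagnostic(coyote_2_missing_1, panel) == "coyote"
        tie = {"diag1": HOM1, "diag2": HOM2, "diag3": MISSING}
        assert species_diagnostic(tie, panel) == "ambiguous"


class TestAlleleFrequenciesAndPid:
    def test_frequency_from_genotypes(self):
        genos = [MultilocusGenotype(s, {"l1": c}, n_autosomal=1)
                 for s, c in [("a", HOM1), ("b", HET), ("c", HOM2)]]
        assert allele_frequencies(genos) == {"l1": pytest.approx(0.5)}

    def test_all_hom1_gives_one(self):
        genos = [MultilocusGenotype(s, {"l1": HOM1}, n_autosomal=1) for s in "ab"]
        assert allele_frequencies(genos)["l1"] == 1.0

    def test_uncalled_locus_excluded(self):
        genos = [MultilocusGenotype("a", {"l1": HOM1, "l2": MISSING}, n_autosomal=2)]
        with pytest.warns(UserWarning, match="l2"):
            freqs = allele_frequencies(genos)
        assert "l2" not in freqs

    @pytest.mark.parametrize("p,expected", [(0.5, 0.375), (1.0, 1.0)])
    def test_pid_locus_values(self, p, expected):
        assert pid_locus([p, 1 - p]) == pytest.approx(expected)

    def test_pid_product_two_loci(self):
        _, product = pid_expected({"l1": 0.5, "l2": 0.5})
        assert product == pytest.approx(0.375 ** 2)

    @pytest.mark.parametrize("p,expected", [(0.5, 0.59375), (1.0, 1.0)])
    def test_pidsib_locus_values(self, p, expected):
        assert pid_sibs_locus([p, 1 - p]) == pytest.approx(expected)

    def test_pidsib_dominates_pid_on_grid(self):
        for p in np.linspace(0.01, 0.99, 50):
            assert pid_sibs_locus([p, 1 - p]) >= pid_locus([p, 1 - p])


class TestMatching:
    def _geno(self, sid, calls35, sex="F"):
        return MultilocusGenotype(
            sid, {f"l{i}": c for i, c in enumerate(calls35)},
            sex=sex, n_autosomal=len(calls35))

    def test_identical_genotypes_merge(self):
        a = self._geno("a", [HOM1] * 35)
        b = self._geno("b", [HOM1] * 35)
        (ind,) = match_individuals([a, b])
        assert ind.sample_ids == ["a", "b"]

    def test_one_mismatch_within_tolerance_merges(self):
        a = self._geno("a", [HOM1] * 35)
        b = self._geno("b", [HET] + [HOM1] * 34)
        assert len(match_individuals([a, b])) == 1

    def test_five_mismatches_stay_distinct(self):
        a = self._geno("a", [HOM1] * 35)
        b = self._geno("b", [HET] * 5 + [HOM1] * 30)
        assert len(match_individuals([a, b])) == 2

    def test_insufficient_shared_loci_no_match(self):
        # identical where co-called, but overlap below the configured floor
        a = self._geno("a", [HOM1] * 30 + [MISSING] * 5)
        b = self._geno("b", [MISSING] * 5 + [HOM1] * 30)
        mism, shared = genotype_distance(a, b)
        assert (mism, shared) == (0, 25)
        assert len(match_individuals([a, b], RunConfig(min_shared_loci=26))) == 2
        assert len(match_individuals([a, b], RunConfig(min_shared_loci=25))) == 1

    def test_sex_conflict_flagged_not_split(self):
        a = self._geno("a", [HOM1] * 35, sex="M")
        b = self._geno("b", [HOM1] * 35, sex="F")
        (ind,) = match_individuals([a, b])
        assert ind.sex_conflict

    def test_detection_history_years(self):
        a = self._geno("a", [HOM1] * 35)
        b = self._geno("b", [HOM1] * 35)
        (ind,) = match_individuals([a, b])
        dates = {"a": pd.Timestamp("2016-07-01"), "b": pd.Timestamp("2018-02-01")}
        (ind,) = detection_history([ind], dates)
        assert ind.years_detected == {2016, 2018}
        assert ind.first_detection == pd.Timestamp("2016-07-01")

    def test_biological_year_switch(self):
        a = self._geno("a", [HOM1] * 35)
        (ind,) = match_individuals([a])
        dates = {"a": pd.Timestamp("2018-02-01")}  # before 1 May -> year 2017
        (ind,) = detection_history([ind], dates, RunConfig(year_mode="biological"))
        assert ind.years_detected == {2017}


class TestGenotypeSamples:
    def test_noise_free_pipeline_recovers_calls(self):
        panel = Panel.default(3)
        truth = {"snp01": HOM1, "snp02": HET, "snp03": HOM2}
        counts_map = {HOM1: (100, 0), HET: (50, 50), HOM2: (0, 100)}
        rows = [("s1", rep, loc, *counts_map[c])
                for loc, c in truth.items() for rep in (1, 2, 3)]
        rows += [("s1", rep, "diag1", 100, 0) for rep in (1, 2, 3)]
        rows += [("s1", rep, "ymark", 80, 0) for rep in (1, 2, 3)]
        counts = pd.DataFrame(rows, columns=["sample_id", "replicate", "locus_id",
                                             "allele1_count", "allele2_count"])
        (geno,) = genotype_samples(counts, panel)
        assert geno.calls == truth
        assert geno.sex == "M" and geno.species == "wolf" and geno.qc_pass


class TestHweExact:
    def test_worked_enumeration_3_hets(self):
        # n=3, all het: possible h in {1, 3} with P = {0.6, 0.4}
        assert hwe_exact(0, 3, 0) == pytest.approx(0.4)

    def test_observed_most_probable_gives_one(self):
        assert hwe_exact(1, 1, 1) == pytest.approx(1.0)

    def test_monomorphic_is_one(self):
        assert hwe_exact(5, 0, 0) == 1.0

    def test_probabilities_sum_to_one_all_configurations(self):
        """Conditional distribution sums to 1 for every (n <= 10, nA)."""
        for n in range(1, 11):
            for n_a in range(0, 2 * n + 1):
                n_b = 2 * n - n_a
                h_max = min(n_a, n_b)
                hs = list(range(h_max % 2, h_max + 1, 2))
                total = 0.0
                for h in hs:
                    aa, bb = (n_a - h) // 2, (n_b - h) // 2
                    total += (math.factorial(n) / (math.factorial(aa)
                              * math.factorial(h) * math.factorial(bb))
                              * 2 ** h * math.factorial(n_a) * math.factorial(n_b)
                              / math.factorial(2 * n))
                assert total == pytest.approx(1.0, abs=1e-12), (n, n_a)


class TestFilterSnps:
    def _matrix(self, cols):
        return pd.DataFrame(cols)

    def test_low_maf_dropped(self):
        m = self._matrix({
            "keep": [0, 1, 2, 1, 0, 1, 2, 1],   # MAF 0.5
            "rare": [0, 0, 0, 0, 0, 0, 0, 1],   # MAF 0.0625 < 0.3
        })
        out = filter_snps(m)
        assert list(out.columns) == ["keep"]

    def test_perfectly_correlated_pair_pruned_to_one(self):
        g = [0, 1, 2, 1, 0, 2, 1, 1]
        m = self._matrix({"a": g, "b": g})
        out = filter_snps(m)
        assert len(out.columns) == 1 and out.columns[0] in {"a", "b"}

    def test_high_missing_sample_dropped(self):
        # independent HWE loci across 30 samples: locus filters keep all,
        # then the 35%-missing sample falls to the sample filter
        rng = np.random.default_rng(8)
        m = pd.DataFrame(
            rng.binomial(2, 0.5, size=(30, 8)).astype(float),
            columns=[f"l{i}" for i in range(8)])
        m.iloc[0, :3] = np.nan  # 3/8 = 37.5% missing > 30%
        out = filter_snps(m)
        assert 0 not in out.index
        assert 1 in out.index

    def test_hwe_violating_locus_dropped(self):
        # strong heterozygote deficit: 10 AA, 0 AB, 10 BB
        bad = [2] * 10 + [0] * 10
        good = [0, 1, 2, 1] * 5
        m = self._matrix({"bad": bad, "good": good})
        out = filter_snps(m)
        assert list(out.columns) == ["good"]

    def test_all_filtered_raises(self):
        m = self._matrix({"rare": [0] * 7 + [1]})
        with pytest.raises(ValueError, match="no loci survive"):
            filter_snps(m)
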