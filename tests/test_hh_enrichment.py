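"""Region arithmetic, enrichment contrasts, Fisher oracle, frequency
classes, iHS windows, distance bins and disease-allele overlaps."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from sweepload import hh_enrichment as hh
from sweepload.hh_enrichment import (RegionSet, distance_bins,
                                     enrichment_from_counts, fisher_one_sided,
                                     freq_class_ratios, ihs_windows,
                                     round_10kb)


def fisher_enumeration(a, b, c, d):
    """Brute-force upper-tail Fisher p over all tables with fixed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d
    total = comb(n, c1)
    p = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        if x >= a:
            p += comb(r1, x) * comb(n - r1, c1 - x) / total
    return p


class TestFisher:
    def test_two_equiprobable_tables(self):
        assert fisher_one_sided(1, 0, 0, 1) == pytest.approx(0.5)

    def test_within_gene_vs_background_counts(self):
        # 11/6 deleterious/neutral within target genes against the summed
        # non-hitchhiking background 12645/31195
        assert fisher_one_sided(11, 6, 12645, 31195) == pytest.approx(
            0.0023, abs=1e-4)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle_on_small_tables(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(0, 9, size=4)
        assert fisher_one_sided(a, b, c, d) == pytest.approx(
            fisher_enumeration(a, b, c, d), abs=1e-12)

    def test_empty_margin_convention(self):
        assert fisher_one_sided(0, 0, 3, 5) == 1.0


class TestRegionSet:
    def test_rounding_preserves_containment(self):
        assert round_10kb(14_999, 3_000_001) == (10_000, 3_010_000)
        for s, e in [(0, 1), (9_999, 10_001), (25_000, 25_001)]:
            rs, re = round_10kb(s, e)
            assert rs <= s and re >= e

    def test_overlapping_intervals_merged(self):
        df = pd.DataFrame({"chrom": ["chr1"] * 2,
                           "start": [100_000, 150_000],
                           "end": [200_000, 320_000]})
        rs = RegionSet.from_frame(df)
        assert rs.n_intervals() == 1
        assert rs.total_length() == 220_000

    def test_contains_and_distance(self):
        rs = RegionSet.from_frame(pd.DataFrame(
            {"chrom": ["chr1"], "start": [100_000], "end": [200_000]}),
            round_to_grid=False)
        chroms = np.array(["chr1"] * 4 + ["chr2"])
        pos = np.array([150_000, 50_000, 250_000, 99_999, 1000])
        inside = rs.contains(chroms, pos)
        assert list(inside) == [True, False, False, False, False]
        d = rs.distance(chroms, pos)
        assert d[0] == 0
        assert d[1] == 50_000
        assert d[2] == pytest.approx(50_001)
        assert np.isinf(d[4])

    def test_distance_matches_brute_force(self, rng):
        starts = np.sort(rng.integers(0, 900_000, size=6))
        df = pd.DataFrame({"chrom": "chr1", "start": starts,
                           "end": starts + 30_000})
        rs = RegionSet.from_frame(df, round_to_grid=False)
        pos = rng.integers(0, 1_000_000, size=50)
        got = rs.distance(np.full(50, "chr1"), pos)
        for p, g in zip(pos, got):
            best = np.inf
            for arr in rs.intervals.values():
                for s, e in arr:
                    if s <= p < e:
                        best = 0
                    else:
                        best = min(best, abs(p - s), abs(p - (e - 1)))
            assert g == pytest.approx(best)


class TestEnrichment:
    def test_reference_rare_class_counts_give_expected_fold(self):
        res = enrichment_from_counts(650, 1013, 5469, 9109)
        assert round(res.ratio_hh, 2) == 0.64
        assert round(res.ratio_out, 2) == 0.60
        assert round(res.fold, 2) == 1.07

    def test_identical_densities_fold_one(self):
        res = enrichment_from_counts(100, 200, 1000, 2000)
        assert res.fold == pytest.approx(1.0)
        assert res.z == pytest.approx(0.0)

    def test_partition_invariant(self, small_snps):
        snps, _ = small_snps
        called = snps[snps.call.isin(["DEL", "NEU"])]
        regions = RegionSet.from_frame(pd.DataFrame(
            {"chrom": ["chr1"], "start": [2_000_000], "end": [9_000_000]}))
        mask = pd.DataFrame({"chrom": ["chr1", "chr2"], "start": [0, 0],
                             "end": [30_000_000, 30_000_000]})
        res = hh.enrichment(called, regions, mask)
        assert res.del_hh + res.del_out == (called.call == "DEL").sum()
        assert res.neu_hh + res.neu_out == (called.call == "NEU").sum()

    def test_fold_reciprocal_under_side_swap(self):
        res = enrichment_from_counts(30, 60, 100, 150)
        swapped = enrichment_from_counts(100, 150, 30, 60)
        assert res.fold == pytest.approx(1 / swapped.fold)

    def test_zero_cds_rejected(self, small_snps):
        snps, _ = small_snps
        regions = RegionSet.from_frame(pd.DataFrame(
            {"chrom": ["chr9"], "start": [0], "end": [100_000]}))
        mask = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        with pytest.raises(ValueError, match="accessible CDS"):
            hh.enrichment(snps, regions, mask)


class TestFreqClasses:
    def test_boundary_is_right_closed(self):
        labels = hh.classify_freq([0.008, 0.0081, 0.059, 0.0591, 1.0, 0.0])
        assert list(labels) == ["rare", "intermediate", "intermediate",
                                "common", "common", ""]

    def test_reference_intermediate_and_common_counts(self):
        inter = enrichment_from_counts(470, 1050, 4241, 10376)
        common = enrichment_from_counts(329, 1206, 2935, 11710)
        assert round(inter.fold, 2) == 1.10
        assert round(common.fold, 2) == 1.09

    def test_per_class_partition(self, rng):
        n = 400
        snps = pd.DataFrame({
            "chrom": "chr1",
            "pos": rng.integers(0, 1_000_000, n),
            "call": rng.choice(["DEL", "NEU"], n),
            "freq": rng.uniform(1e-4, 1.0, n)})
        regions = RegionSet.from_frame(pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [500_000]}),
            round_to_grid=False)
        out = freq_class_ratios(snps, regions)
        total = sum(r.del_hh + r.neu_hh + r.del_out + r.neu_out
                    for r in out.values())
        assert total == n


class TestIhsWindows:
    def _scores(self, rng, n_windows=250, per_window=20):
        pos = np.concatenate([
            w * 100_000 + rng.integers(0, 100_000, per_window)
            for w in range(n_windows)])
        return pd.DataFrame({"chrom": "chr1", "pos": pos,
                             "ihs": rng.normal(0, 1, len(pos))})

    def test_fraction_and_small_window_exclusion(self, rng):
        ihs = pd.DataFrame({
            "chrom": "chr1",
            "pos": np.r_[np.arange(20) * 1000, 100_000 + np.arange(9) * 1000],
            "ihs": np.r_[np.full(3, 3.0), np.zeros(17), np.full(9, 3.0)]})
        tab, _ = ihs_windows(ihs, cutoff=0.05)
        nine = tab[tab.n_snps == 9]
        assert (nine["excluded"] == "fewer_than_10_snps").all()
        twenty = tab[tab.n_snps == 20]
        assert twenty["fraction"].iloc[0] == pytest.approx(0.15)

    def test_top_fraction_selected_per_bin_with_ties(self, rng):
        tab, regions = ihs_windows(self._scores(rng), cutoff=0.05)
        kept = tab[tab["excluded"] == ""]
        for _, grp in kept.groupby("snp_bin"):
            sel = grp[grp.selected]
            unsel = grp[~grp.selected]
            assert len(sel) >= np.ceil(0.05 * len(grp))
            if len(sel) and len(unsel):
                # every selected window beats every unselected one
                assert sel["fraction"].min() > unsel["fraction"].max()
        assert regions.n_intervals() >= 1

    def test_small_bins_excluded(self, rng):
        tab, _ = ihs_windows(self._scores(rng, n_windows=50), cutoff=0.05)
        assert (tab["excluded"] == "bin_too_small").all()
        assert not tab["selected"].any()


class TestDistanceBins:
    def _setup(self):
        regions = RegionSet.from_frame(pd.DataFrame(
            {"chrom": ["chr1"], "start": [1_000_000], "end": [1_500_000]}),
            round_to_grid=False)
        snps = pd.DataFrame({
            "chrom": "chr1",
            "pos": [1_200_000, 850_000, 450_000, 100_000],
            "call": ["DEL", "NEU", "DEL", "NEU"]})
        return snps, regions

    def test_binning_and_region_flag(self):
        snps, regions = self._setup()
        out = distance_bins(snps, regions)
        region_bin = out[out["in_region"]]
        assert region_bin["DEL"].iloc[0] == 1
        b0 = out[(out["bin"] == 0) & ~out["in_region"]]
        assert b0["NEU"].iloc[0] == 1  # 150 kb away -> [0, 200 kb)
        b2 = out[(out["bin"] == 2) & ~out["in_region"]]
        assert b2["DEL"].iloc[0] == 1  # 550 kb away -> [400, 600 kb)


class TestDiseaseOverlap:
    def test_missing_frequency_is_rare_and_ratios(self):
        regions = RegionSet.from_frame(pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [500_000]}),
            round_to_grid=False)
        alleles = pd.DataFrame({
            "chrom": "chr1",
            "pos": [100_000, 600_000, 700_000, 200_000],
            "category": ["omim", "omim", "gwas", "gwas"],
            "freq": [np.nan, 0.2, np.nan, 0.3],
        })
        out = hh.disease_overlap(alleles, regions)
        assert out["categories"]["omim"]["ratio"] == pytest.approx(1.0)
        assert out["categories"]["gwas"]["ratio"] == pytest.approx(1.0)

    def test_all_outside_gives_zero_ratios(self):
        regions = RegionSet.from_frame(pd.DataFrame(
            {"chrom": ["chr2"], "start": [0], "end": [10_000]}),
            round_to_grid=False)
        alleles = pd.DataFrame({"chrom": "chr1", "pos": [1, 2, 3],
                                "category": "omim", "freq": 0.1})
        out = hh.disease_overlap(alleles, regions)
        assert out["categories"]["omim"]["ratio"] == 0.0

    def test_identical_freq_distributions_rank_sum_large_p(self, rng):
        regions = RegionSet.from_frame(pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [500_000]}),
            round_to_grid=False)
        freqs = np.tile(np.linspace(0.01, 0.5, 50), 2)
        alleles = pd.DataFrame({
            "chrom": "chr1",
            "pos": np.r_[np.full(50, 100), np.full(50, 900_000)],
            "category": "omim", "freq": freqs})
        out = hh.disease_overlap(alleles, regions)
        assert out["freq_ranksum_p"] > 0.5
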