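"""Window rates, GC-stratified offsets, and the binomial GLMs checked
against an independent IRLS implementation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from sweepload import genome_windows as gw


def irls_binomial(endog: np.ndarray, exog: np.ndarray,
                  offset: np.ndarray | None = None, n_iter: int = 60) -> np.ndarray:
    """Independent Newton-Raphson/IRLS oracle for the binomial GLM."""
    y, n_tot = endog[:, 0], endog.sum(axis=1)
    off = np.zeros(len(y)) if offset is None else offset
    beta = np.zeros(exog.shape[1])
    for _ in range(n_iter):
        eta = off + exog @ beta
        mu = expit(eta)
        w = n_tot * mu * (1 - mu)
        z = eta - off + (y - n_tot * mu) / np.maximum(w, 1e-12)
        wx = exog * w[:, None]
        beta = np.linalg.solve(exog.T @ wx, wx.T @ z)
    return beta


def _random_cells(rng, n_bins=10, beta0=-0.3, beta1=-0.1, n_per_cell=2000):
    rows = []
    for i in range(1, n_bins + 1):
        r = 0.3 * i
        for j in range(4):
            s = float(np.clip(0.15 + 0.08 * j + rng.normal(0, 0.02), 0.02, 0.9))
            p = expit(logit(s) + beta0 + beta1 * r)
            d = rng.binomial(n_per_cell, p)
            rows.append({"rec_bin": i, "gc_class": j, "r_i": r, "s_ij": s,
                         "DEL": int(d), "NEU": int(n_per_cell - d),
                         "missing": False})
    return pd.DataFrame(rows)


class TestWindowRecRate:
    def test_rate_from_most_distant_pair(self):
        rate, reason = gw.window_rec_rate([0, 400_000], [0.0, 0.4])
        assert rate == pytest.approx(1.0) and reason == ""

    def test_short_span_excluded(self):
        rate, reason = gw.window_rec_rate([10_000, 310_000], [0.0, 0.5])
        assert np.isnan(rate) and reason == "snp_span_le_360kb"

    def test_flat_map_rate_zero_retained(self):
        rate, reason = gw.window_rec_rate([0, 399_000], [0.7, 0.7])
        assert rate == 0.0 and reason == ""

    def test_unsorted_map_raises(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            gw.window_rec_rate([0, 200_000, 400_000], [0.5, 0.2, 0.6])


class TestBuildWindows:
    def test_exclusion_reasons_and_binning(self, small_genome):
        win = gw.build_windows(small_genome.map_snps, small_genome.genetic_map,
                               small_genome.chrom_ends, small_genome.mask)
        assert (win["reason"] == "near_chromosome_end").sum() > 0
        kept = gw.assign_rec_bins(win)
        sizes = kept.groupby("rec_bin").size()
        assert len(sizes) == 10
        assert sizes.max() - sizes.min() <= 1  # equal-sized bins
        # bins ordered by rate
        means = kept.groupby("rec_bin")["rec_rate"].max()
        assert (means.diff().dropna() >= -1e-12).all()


class TestOffset:
    def _cells(self, fcon_ij):
        rows = []
        for i, f in enumerate(fcon_ij, start=1):
            rows.append({"rec_bin": i, "gc_class": 2, "r_i": float(i),
                         "DEL": 30, "NEU": 70, "codons": 1000,
                         "conserved_codons": int(1000 * f)})
        return pd.DataFrame(rows)

    def test_constant_conservation_reduces_to_class_baseline(self):
        cells = gw.compute_offset(self._cells([0.4, 0.4, 0.4]))
        assert np.allclose(cells["s_ij"], 0.3)  # fdel_j = 30/100

    def test_double_conservation_doubles_offset(self):
        cells = gw.compute_offset(self._cells([0.2, 0.2, 0.8]))
        # fcon_j = 0.4, fdel_j = 0.3: bin 3 has fcon_ij = 2 fcon_j -> 0.6
        assert cells.loc[cells.rec_bin == 3, "s_ij"].iloc[0] == pytest.approx(0.6)

    def test_zero_deleterious_class_clipped_to_eps(self):
        cells = self._cells([0.4, 0.4, 0.4])
        cells["DEL"] = 0
        out = gw.compute_offset(cells)
        assert np.allclose(out["s_ij"], gw.OFFSET_EPS)

    def test_empty_cell_flagged_missing(self):
        cells = self._cells([0.4, 0.4, 0.4])
        cells.loc[0, ["codons", "conserved_codons"]] = 0
        out = gw.compute_offset(cells)
        assert bool(out.loc[0, "missing"])


class TestRecombinationModel:
    def test_matches_independent_irls_to_1e6(self, rng):
        cells = _random_cells(rng)
        fit = gw.fit_recombination_model(cells)
        exog = np.column_stack([np.ones(len(cells)), cells["r_i"]])
        offset = logit(cells["s_ij"].to_numpy())
        beta = irls_binomial(cells[["DEL", "NEU"]].to_numpy(), exog, offset)
        assert fit.params["beta0"] == pytest.approx(beta[0], abs=1e-6)
        assert fit.params["beta1"] == pytest.approx(beta[1], abs=1e-6)

    def test_recovers_negative_slope(self, rng):
        cells = _random_cells(rng, beta1=-0.1, n_per_cell=20000)
        fit = gw.fit_recombination_model(cells)
        lo, hi = fit.conf_int["beta1"]
        assert lo < -0.1 < hi

    def test_constant_proportions_give_null_slope(self):
        rows = [{"rec_bin": i, "gc_class": 0, "r_i": float(i), "s_ij": 0.5,
                 "DEL": 300, "NEU": 700, "missing": False}
                for i in range(1, 11)]
        fit = gw.fit_recombination_model(pd.DataFrame(rows))
        assert abs(fit.params["beta1"]) < 1e-8
        assert fit.pvalues["beta1"] > 0.99

    def test_offset_half_equals_plain_fit(self, rng):
        cells = _random_cells(rng)
        cells["s_ij"] = 0.5  # logit(0.5) = 0: offset vanishes
        fit = gw.fit_recombination_model(cells)
        beta = irls_binomial(cells[["DEL", "NEU"]].to_numpy(),
                             np.column_stack([np.ones(len(cells)), cells["r_i"]]))
        assert fit.params["beta1"] == pytest.approx(beta[1], abs=1e-6)

    def test_single_bin_rejected(self):
        cells = pd.DataFrame([{"rec_bin": 1, "gc_class": 0, "r_i": 1.0,
                               "s_ij": 0.3, "DEL": 5, "NEU": 5, "missing": False}])
        with pytest.raises(gw.DegenerateDesignError):
            gw.fit_recombination_model(cells)


class TestHitchhikingModel:
    def _cells(self, rng, beta2=0.15, n=4000):
        rows = []
        for h in (0, 1):
            for i in range(1, 11):
                r = 0.3 * i
                s = 0.3
                p = expit(logit(s) - 0.05 * r + beta2 * h)
                d = rng.binomial(n, p)
                rows.append({"rec_bin": i, "gc_class": 0, "h": h, "r_i": r,
                             "s_ij": s, "DEL": int(d), "NEU": int(n - d),
                             "missing": False})
        return pd.DataFrame(rows)

    def test_recovers_indicator_effect(self, rng):
        fit = gw.fit_hitchhiking_model(self._cells(rng, beta2=0.15))
        lo, hi = fit.conf_int["beta2"]
        assert lo < 0.15 < hi
        assert fit.params["beta2"] > 0

    def test_matches_irls_oracle(self, rng):
        cells = self._cells(rng)
        fit = gw.fit_hitchhiking_model(cells)
        exog = np.column_stack([np.ones(len(cells)), cells["r_i"], cells["h"]])
        beta = irls_binomial(cells[["DEL", "NEU"]].to_numpy(), exog,
                             logit(cells["s_ij"].to_numpy()))
        for k, name in enumerate(["beta0", "beta1", "beta2"]):
            assert fit.params[name] == pytest.approx(beta[k], abs=1e-6)

    def test_permuted_indicator_centres_on_zero(self, rng):
        cells = self._cells(rng, beta2=0.0)
        betas = []
        for _ in range(20):
            perm = cells.copy()
            perm["h"] = rng.permutation(perm["h"].to_numpy())
            try:
                betas.append(gw.fit_hitchhiking_model(perm).params["beta2"])
            except gw.DegenerateDesignError:
                continue
        assert abs(np.mean(betas)) < 0.02

    def test_missing_group_rejected(self, rng):
        cells = self._cells(rng)
        with pytest.raises(gw.DegenerateDesignError):
            gw.fit_hitchhiking_model(cells[cells.h == 0])


class TestDistanceModel:
    def test_decay_sign_recovered(self, rng):
        d = np.arange(20) * 0.2 + 0.1
        p = expit(-0.3 - 0.5 * d)
        dels = rng.binomial(3000, p)
        binned = pd.DataFrame({"d_k": d, "DEL": dels, "NEU": 3000 - dels})
        fit = gw.fit_distance_model(binned)
        assert fit.params["beta1"] == pytest.approx(-0.5, rel=0.2)
        assert fit.pvalues["beta1"] < 1e-6

    def test_flat_ratio_gives_null_slope(self):
        binned = pd.DataFrame({"d_k": np.arange(10) * 0.2,
                               "DEL": 300, "NEU": 700})
        fit = gw.fit_distance_model(binned)
        assert abs(fit.params["beta1"]) < 1e-8

    def test_single_bin_rejected(self):
        with pytest.raises(gw.DegenerateDesignError):
            gw.fit_distance_model(pd.DataFrame({"d_k": [0.1], "DEL": [5],
                                                "NEU": [5]}))


class TestBgcFilter:
    def test_filter_rules(self):
        snps = pd.DataFrame({
            "ancestral": ["A", "G", "A", "C", "N"],
            "derived": ["G", "A", "C", "T", "A"],
            "gc_class": [2, 2, 0, 1, 2],
        })
        kept, counts = gw.bgc_filter(snps)
        # A->G excluded (AT-to-GC); G->A retained; A->C in gc0 excluded twice
        # over (AT-to-GC wins the accounting); C->T retained; N dropped
        assert counts["at_to_gc"] == 2
        assert counts["unknown_ancestral"] == 1
        assert list(kept["ancestral"]) == ["G", "C"]

    def test_gc_zero_codon_excluded(self):
        snps = pd.DataFrame({"ancestral": ["G"], "derived": ["A"],
                             "gc_class": [0]})
        kept, counts = gw.bgc_filter(snps)
        assert kept.empty and counts["gc_class_0"] == 1


def test_codon_gc_class():
    assert gw.codon_gc_class("AAA") == 0
    assert gw.codon_gc_class("ATG") == 1
    assert gw.codon_gc_class("GCC") == 3
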