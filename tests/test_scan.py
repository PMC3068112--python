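"""Interval mapping: expected genotypes, LOD, thresholds, intervals,
classification and the two-QTL ghost check."""

import math

import numpy as np
import pandas as pd
import pytest

from budqtl import scan as sc
from budqtl import simulate as sim

from conftest import single_parent_map
from oracles import em_mixture_lod


class TestExpectedGenotype:
    def test_observed_marker_is_definitive(self, dense_map):
        geno = sim.simulate_progeny(dense_map, 100, 1, missing_rate=0.1)
        pos = dense_map["position_cM"].to_numpy()
        g = geno.maternal.to_numpy()
        E = sc.expected_genotype(pos, g, pos)
        obs = ~np.isnan(g)
        assert np.array_equal(E[obs], g[obs])

    def test_no_information_gives_half(self):
        E = sc.expected_genotype(np.array([0.0, 20.0]),
                                 np.array([[np.nan, np.nan]]), np.array([10.0]))
        assert E[0, 0] == pytest.approx(0.5)

    def test_midpoint_between_discordant_flanks(self):
        E = sc.expected_genotype(np.array([0.0, 20.0]),
                                 np.array([[0.0, 1.0]]), np.array([10.0]))
        assert E[0, 0] == pytest.approx(0.5)

    def test_probabilities_bounded(self, dense_map):
        geno = sim.simulate_progeny(dense_map, 80, 2, missing_rate=0.2)
        pos = dense_map["position_cM"].to_numpy()
        grid = sc.make_grid(pos, 1.0)
        E = sc.expected_genotype(pos, geno.maternal.to_numpy(), grid)
        assert np.all((E >= 0.0) & (E <= 1.0))


class TestLod:
    def test_constant_response_zero_everywhere(self, dense_map):
        geno = sim.simulate_progeny(dense_map, 60, 3, missing_rate=0.0)
        pos = dense_map["position_cM"].to_numpy()
        grid = sc.make_grid(pos, 2.0)
        E = sc.expected_genotype(pos, geno.maternal.to_numpy(), grid)
        lod, ppve, _ = sc._lod_from_expectation(E, np.full(60, 7.0))
        assert np.allclose(lod, 0.0)

    def test_four_progeny_closed_form(self):
        # genotype 0: {10, 12}; genotype 1: {14, 16}: RSS0=20, RSS1=4
        E = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([10.0, 12.0, 14.0, 16.0])
        lod, ppve, effect = sc._lod_from_expectation(E, y)
        assert lod[0] == pytest.approx(2 * math.log10(5), abs=1e-9)
        assert ppve[0] == pytest.approx(80.0)
        assert effect[0] == pytest.approx(4.0)

    def test_affine_invariance(self, dense_map):
        geno = sim.simulate_progeny(dense_map, 120, 4, missing_rate=0.0)
        pos = dense_map["position_cM"].to_numpy()
        grid = sc.make_grid(pos, 2.0)
        E = sc.expected_genotype(pos, geno.maternal.to_numpy(), grid)
        y = np.random.default_rng(5).normal(size=120)
        lod1, _, _ = sc._lod_from_expectation(E, y)
        lod2, _, _ = sc._lod_from_expectation(E, 3.0 * y - 17.0)
        assert np.allclose(lod1, lod2)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_em_mixture_oracle(self, dense_map, seed):
        """Regression LOD tracks the mixture-ML LOD for a typical
        small-effect QTL (PPVE ~5%) on a dense map."""
        n = 250
        geno = sim.simulate_progeny(dense_map, n, 100 + seed, missing_rate=0.0)
        rng = np.random.default_rng(200 + seed)
        x = geno.maternal.iloc[:, 6].to_numpy()
        y = 0.459 * (x - 0.5) + rng.normal(0, 1, n)
        pos = dense_map["position_cM"].to_numpy()
        grid = sc.make_grid(pos, 2.0)
        E = sc.expected_genotype(pos, geno.maternal.to_numpy(), grid)
        lod_hk, _, _ = sc._lod_from_expectation(E, y)
        lod_em = np.array([em_mixture_lod(E[:, j], y) for j in range(len(grid))])
        assert np.abs(lod_hk - lod_em).max() <= 0.2


class TestThresholds:
    def test_order_statistic_rule_small_n(self):
        maxima = np.arange(19.0)
        # alpha=0.05, n=19 -> ceil(0.95*20) = 19th order statistic = maximum
        assert sc.order_statistic_threshold(maxima, 0.05) == 18.0

    def test_chromosome_at_most_genome(self, small_true_map):
        geno = sim.simulate_progeny(small_true_map, 150, 6, missing_rate=0.0)
        mspec = sim.true_map_spec(small_true_map, "maternal")
        y = pd.Series(np.random.default_rng(7).normal(size=150),
                      index=geno.maternal.index)
        chrom, genome = sc.permutation_thresholds(
            mspec, geno.maternal, y, n_perm=150, seed=3, step=2.0, reporting=False)
        for t in chrom.values():
            assert t.threshold <= genome.threshold + 1e-12

    def test_reproducible_under_seed(self, small_true_map):
        geno = sim.simulate_progeny(small_true_map, 100, 8, missing_rate=0.0)
        mspec = sim.true_map_spec(small_true_map, "maternal")
        y = pd.Series(np.random.default_rng(9).normal(size=100),
                      index=geno.maternal.index)
        a = sc.permutation_thresholds(mspec, geno.maternal, y, n_perm=120,
                                      seed=5, step=2.0, reporting=False)
        b = sc.permutation_thresholds(mspec, geno.maternal, y, n_perm=120,
                                      seed=5, step=2.0, reporting=False)
        assert a[1].threshold == b[1].threshold

    def test_reporting_mode_requires_1000(self, small_true_map):
        geno = sim.simulate_progeny(small_true_map, 100, 8, missing_rate=0.0)
        mspec = sim.true_map_spec(small_true_map, "maternal")
        y = pd.Series(np.zeros(100), index=geno.maternal.index)
        with pytest.raises(ValueError, match="1,000"):
            sc.permutation_thresholds(mspec, geno.maternal, y, n_perm=200, seed=1)


class TestSupportInterval:
    def _triangular_profile(self):
        grid = np.arange(0.0, 101.0, 1.0)
        lod = 4.0 - 0.2 * np.abs(grid - 50.0)
        return sc.LodProfile("d", "I", grid, np.maximum(lod, 0.0), 100)

    def test_triangular_drops(self):
        p = self._triangular_profile()
        assert sc.support_interval(p, 1.0) == pytest.approx((45.0, 55.0))
        assert sc.support_interval(p, 2.0) == pytest.approx((40.0, 60.0))

    def test_peak_at_group_end_one_sided(self):
        grid = np.arange(0.0, 51.0, 1.0)
        lod = 5.0 - 0.1 * grid
        p = sc.LodProfile("d", "I", grid, lod, 100)
        lo, hi = sc.support_interval(p, 1.0)
        assert lo == 0.0 and hi == pytest.approx(10.0)

    def test_flat_profile_spans_group(self):
        grid = np.arange(0.0, 31.0, 1.0)
        p = sc.LodProfile("d", "I", grid, np.full_like(grid, 2.0), 50)
        with pytest.warns(UserWarning, match="flat"):
            assert sc.support_interval(p, 1.0) == (0.0, 30.0)


class TestClassification:
    def _profile(self, peak):
        grid = np.arange(0.0, 41.0, 1.0)
        lod = np.maximum(peak - 0.2 * np.abs(grid - 20.0), 0.0)
        return sc.LodProfile("d", "I", grid, lod, 200)

    @pytest.mark.parametrize("peak,expected", [
        (5.0, sc.SIGNIFICANT), (3.5, sc.SUGGESTIVE), (2.0, sc.INDICATIVE)])
    def test_threshold_classes(self, peak, expected):
        rec = sc.classify_qtl(self._profile(peak), {"ppve_pct": 5.0, "effect": 1.0},
                              chrom_threshold=3.2, genome_threshold=4.1)
        assert rec.qtl_class == expected
        assert rec.ci1[0] <= rec.peak_cM <= rec.ci1[1]
        assert rec.ci2[0] <= rec.ci1[0] and rec.ci1[1] <= rec.ci2[1]

    def test_retain_indicative_rule(self):
        def rec(group, lo, hi):
            return {"group": group, "ci1": (lo, hi)}
        sig = [rec("I", 10, 20), rec("I", 15, 25), rec("II", 0, 10)]
        keep2 = sc.retain_indicative([rec("I", 18, 22)], sig)
        keep1 = sc.retain_indicative([rec("II", 5, 8)], sig)
        keep0 = sc.retain_indicative([rec("III", 0, 5)], sig)
        assert len(keep2) == 1 and keep1 == [] and keep0 == []


class TestPhenotypeForScan:
    def test_clone_mean(self):
        h = pd.DataFrame({
            "tree_id": np.repeat([f"t{i}" for i in range(25)], 6),
            "site": "VES", "year": 2004,
            "height_mm": np.tile([10.0, 11, 12, 13, 14, 15], 25),
        })
        resp = sc.phenotype_for_scan(heights=h, site="VES", year=2004)
        assert resp.iloc[0] == pytest.approx(12.5)
        assert len(resp) == 25

    def test_missing_clone_absent(self):
        h = pd.DataFrame({
            "tree_id": np.repeat([f"t{i}" for i in range(25)], 2),
            "site": "VES", "year": 2004,
            "height_mm": [np.nan] * 2 + [10.0] * 48,
        })
        resp = sc.phenotype_for_scan(heights=h, site="VES", year=2004)
        assert "t0" not in resp.index


class TestTwoQtl:
    def _scan_inputs(self, qtl_cols, betas, seed, n=350):
        tmap = single_parent_map(np.arange(0.0, 101.0, 10.0))
        geno = sim.simulate_progeny(tmap, n, seed, missing_rate=0.0)
        rng = np.random.default_rng(seed + 1000)
        y = rng.normal(0, 1, n)
        for col, b in zip(qtl_cols, betas):
            y = y + b * (geno.maternal.iloc[:, col].to_numpy() - 0.5)
        posn = sim.true_map_spec(tmap, "maternal").group_positions("I")
        return posn, geno.maternal, pd.Series(y, index=geno.maternal.index)

    def test_single_qtl_keeps_one(self):
        decisions = []
        for seed in range(8):
            posn, g, y = self._scan_inputs([5], [0.667], 40 + seed)
            out = sc.two_qtl_test(posn, g, y, single_threshold=2.0,
                                  n_perm=100, seed=seed)
            decisions.append(out["decision"])
        assert decisions.count(1) >= 7  # >= ~90% specificity

    def test_two_distant_qtls_found(self):
        hits = 0
        for seed in range(8):
            posn, g, y = self._scan_inputs([2, 8], [0.5, 0.5], 60 + seed, n=500)
            out = sc.two_qtl_test(posn, g, y, single_threshold=2.0,
                                  n_perm=100, seed=seed)
            hits += out["decision"] == 2
        assert hits >= 6  # >= 70% power

    def test_null_group_reports_zero(self):
        posn, g, y = self._scan_inputs([], [], 80)
        out = sc.two_qtl_test(posn, g, y, single_threshold=2.5, n_perm=100, seed=0)
        assert out["decision"] == 0

    def test_short_group_refused(self):
        tmap = single_parent_map([0.0, 10.0, 20.0])
        geno = sim.simulate_progeny(tmap, 100, 1, missing_rate=0.0)
        posn = sim.true_map_spec(tmap, "maternal").group_positions("I")
        y = pd.Series(np.random.default_rng(0).normal(size=100),
                      index=geno.maternal.index)
        out = sc.two_qtl_test(posn, geno.maternal, y, single_threshold=2.0)
        assert out["decision"] is None
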