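"""The synthetic study-design generator: meiosis, design, phenotypes, truth."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from budqtl import io as io_mod
from budqtl import pheno
from budqtl import simulate as sim
from budqtl.linkage import inverse_kosambi

from conftest import single_parent_map


class TestMapConfig:
    def test_conservation_of_groups_and_length(self):
        cfg = sim.TrueMapConfig(seed=1)
        tmap = sim.simulate_parents_and_map(cfg)
        assert tmap["group"].nunique() == 12
        assert sum(cfg.group_lengths) == pytest.approx(2100.0)
        for _, sub in tmap.groupby("group"):
            assert np.all(np.diff(sub["position_cM"]) > 0)

    def test_all_maternal_config(self):
        cfg = sim.TrueMapConfig(n_groups=1, group_lengths=(50.0,), markers_per_group=3,
                                class_mix=(1.0, 0.0, 0.0), seed=0)
        tmap = sim.simulate_parents_and_map(cfg)
        # tiny groups still reserve anchors for mergeability, the rest is maternal
        assert set(tmap["seg_class"]) <= {"maternal", "anchor"}
        assert (tmap["seg_class"] == "maternal").sum() >= 1

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            sim.TrueMapConfig(n_groups=1, group_lengths=(-5.0,), markers_per_group=3)
        with pytest.raises(ValueError):
            sim.TrueMapConfig(n_groups=1, group_lengths=(50.0,), markers_per_group=0)
        with pytest.raises(ValueError):
            sim.TrueMapConfig(n_groups=1, group_lengths=(50.0,),
                              markers_per_group=3, class_mix=(0.5, 0.2, 0.2))

    def test_determinism_same_seed(self):
        cfg = sim.TrueMapConfig(n_groups=2, group_lengths=(80.0, 80.0),
                                markers_per_group=10, seed=7)
        a = sim.simulate_parents_and_map(cfg)
        b = sim.simulate_parents_and_map(cfg)
        pd.testing.assert_frame_equal(a, b)


class TestMeiosis:
    def test_zero_distance_no_recombinants(self):
        tmap = single_parent_map([10.0, 10.0])
        geno = sim.simulate_progeny(tmap, 500, 3, missing_rate=0.0)
        g = geno.maternal.to_numpy()
        assert np.all(g[:, 0] == g[:, 1])

    def test_kosambi_distance_recovers_theta(self):
        tmap = single_parent_map([0.0, 21.2])
        geno = sim.simulate_progeny(tmap, 5000, 7, missing_rate=0.0)
        g = geno.maternal.to_numpy()
        rec = (g[:, 0] != g[:, 1]).mean()
        expected = inverse_kosambi(21.2)
        se = math.sqrt(expected * (1 - expected) / 5000)
        assert abs(rec - expected) <= 3 * se

    def test_unlinked_groups_independent(self):
        cfg = sim.TrueMapConfig(n_groups=2, group_lengths=(50.0, 50.0),
                                markers_per_group=2, class_mix=(1.0, 0.0, 0.0), seed=2)
        tmap = sim.simulate_parents_and_map(cfg)
        geno = sim.simulate_progeny(tmap, 5000, 8, missing_rate=0.0)
        g = geno.maternal
        m_first = {grp: sub["marker"].iloc[0] for grp, sub in tmap.groupby("group")
                   if sub["marker"].iloc[0] in g.columns}
        a, b = (g[m] for m in list(m_first.values())[:2])
        rec = (a != b).mean()
        assert abs(rec - 0.5) <= 3 * math.sqrt(0.25 / 5000)

    def test_undistorted_markers_pass_1_to_1(self):
        cfg = sim.TrueMapConfig(n_groups=2, group_lengths=(100.0, 100.0),
                                markers_per_group=20, seed=3)
        tmap = sim.simulate_parents_and_map(cfg)
        passes = trials = 0
        for rep in range(5):
            geno = sim.simulate_progeny(tmap, 400, 20 + rep, missing_rate=0.0)
            for table in (geno.maternal, geno.paternal):
                n1 = (table == 1).sum(axis=0).to_numpy()
                n = table.notna().sum(axis=0).to_numpy()
                chi2 = (2 * n1 - n) ** 2 / n
                p = stats.chi2.sf(chi2, df=1)
                passes += int((p >= 0.01).sum())
                trials += len(p)
        assert passes / trials >= 0.98

    def test_distorted_marker_biased(self):
        tmap = single_parent_map([0.0, 30.0])
        mk = tmap["marker"].iloc[0]
        geno = sim.simulate_progeny(tmap, 2000, 5, missing_rate=0.0,
                                    distorted_markers={mk: 0.7})
        frac = geno.maternal[mk].mean()
        assert abs(frac - 0.7) < 0.05

    def test_n_progeny_floor(self):
        tmap = single_parent_map([0.0, 10.0])
        with pytest.raises(ValueError):
            sim.simulate_progeny(tmap, 1, 0)


class TestPhenotypes:
    def _noise_free_design(self, n=12):
        return sim.TrialDesign(
            n_progeny=n, years=(2004,), timing_sd_days=0.0, stage_jitter_sd_days=0.0,
            block_sd_days=0.0, year_sd_days=0.0, site_shift_days=0.0,
            height_sd_mm=0.0, height_block_sd_mm=0.0, height_year_sd_mm=0.0,
        )

    def test_zero_variance_gives_identical_series(self):
        tmap = single_parent_map([0.0, 50.0])
        design = self._noise_free_design()
        cross = sim.simulate_cross("Z", None, design, 3, qtls=[], true_map=tmap,
                                   missing_rate=0.0)
        per_tree = cross.phenology.groupby("tree_id")["stage"].apply(tuple)
        assert per_tree.nunique() == 1
        assert cross.heights["height_mm"].nunique() == 1

    def test_stage_sequences_monotone_and_in_scale(self, small_cross):
        cross, _ = small_cross
        phen = cross.phenology
        for trait, n_stages in (("bud_flush", 6), ("bud_set", 5)):
            sub = phen[phen["trait"] == trait]
            assert sub["stage"].between(0, n_stages).all()
        key = ["tree_id", "ramet", "year", "trait"]
        sorted_ = phen.sort_values(key + ["date"])
        diffs = sorted_.groupby(key)["stage"].diff().dropna()
        assert (diffs >= 0).all()

    def test_unknown_trait_qtl_rejected(self):
        with pytest.raises(ValueError):
            sim.PlantedQtl("seed_mass", "I", 10.0, "maternal", 0.5)

    def test_ppve_recovery_at_marker(self):
        tmap = single_parent_map(np.arange(0.0, 101.0, 10.0))
        design = sim.TrialDesign(n_progeny=500, years=(2004,))
        mk = tmap["marker"].iloc[5]
        qtl = sim.PlantedQtl("height", "I", float(tmap["position_cM"].iloc[5]),
                             "maternal", sim.effect_for_ppve(10.0, design, "height"))
        cross = sim.simulate_cross("P", None, design, 21, qtls=[qtl], true_map=tmap,
                                   missing_rate=0.0)
        h = cross.heights[(cross.heights["site"] == "VES")]
        means = h.groupby("tree_id")["height_mm"].mean()
        x = cross.genotypes.maternal[mk].loc[means.index]
        r2 = np.corrcoef(x, means)[0, 1] ** 2
        assert 100 * r2 == pytest.approx(10.0, abs=3.0)

    def test_repeatability_target_recovered(self):
        tmap = single_parent_map([0.0, 50.0])
        design = sim.TrialDesign(n_progeny=320, years=(2004,),
                                 repeatability={"bud_flush": 0.45, "bud_set": 0.43,
                                                "height": 0.50})
        cross = sim.simulate_cross("R", None, design, 31, qtls=[], true_map=tmap)
        h = cross.heights
        r = pheno.clonal_repeatability(h["height_mm"].to_numpy(), h["tree_id"].to_numpy())
        assert 0.45 <= r <= 0.55

    def test_truth_round_trips(self, tmp_path, small_cross):
        cross, qtl = small_cross
        path = tmp_path / "truth.json"
        io_mod.write_truth(cross.truth, path)
        back = io_mod.read_truth(path)
        rec = back["qtls"][0]
        assert rec["trait"] == qtl.trait
        assert rec["group"] == qtl.group
        assert rec["position_cM"] == qtl.position_cM
        assert rec["effect_sd"] == pytest.approx(qtl.effect_sd)

    def test_determinism_end_to_end(self, small_true_map):
        design = sim.TrialDesign(n_progeny=40, years=(2004,))
        a = sim.simulate_cross("D", None, design, 9, true_map=small_true_map)
        b = sim.simulate_cross("D", None, design, 9, true_map=small_true_map)
        pd.testing.assert_frame_equal(a.genotypes.maternal, b.genotypes.maternal)
        pd.testing.assert_frame_equal(a.phenology, b.phenology)
        pd.testing.assert_frame_equal(a.heights, b.heights)
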