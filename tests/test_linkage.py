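"""Two-point estimation, grouping, ordering, merging, colinearity."""

import math

import numpy as np
import pandas as pd
import pytest

from budqtl import linkage as lk
from budqtl import simulate as sim
from budqtl.linkage import LinkageMapSpec, MarkerGenotypes

from oracles import best_order_exhaustive, two_point_lod_numeric


def _mk(marker, calls, cls="maternal"):
    return MarkerGenotypes(marker, cls, np.asarray(calls))


class TestKosambi:
    def test_zero_and_closed_form(self):
        assert lk.kosambi_cm(0.0) == 0.0
        assert lk.kosambi_cm(0.2) == pytest.approx(21.18, abs=0.005)

    def test_round_trip_identity(self):
        for theta in (0.05, 0.2, 0.37, 0.49):
            assert lk.inverse_kosambi(lk.kosambi_cm(theta)) == pytest.approx(theta, abs=1e-10)

    def test_unlinked_is_infinite(self):
        assert np.isinf(lk.kosambi_cm(0.5))


class TestTwoPoint:
    def test_identical_vectors(self):
        calls = np.tile([0, 1], 25)
        est = lk.two_point(_mk("a", calls), _mk("b", calls))
        assert est.theta == 0.0
        assert est.lod == pytest.approx(50 * math.log10(2), abs=1e-9)

    def test_two_recombinants_of_ten(self):
        est = lk.two_point(_mk("a", [0] * 10), _mk("b", [0] * 8 + [1] * 2))
        assert est.theta == pytest.approx(0.2)
        assert est.lod == pytest.approx(0.837, abs=5e-4)

    @pytest.mark.parametrize("k,n", [(0, 50), (2, 10), (5, 40), (12, 100), (30, 80)])
    def test_matches_numeric_likelihood_oracle(self, k, n):
        theta_o, lod_o = two_point_lod_numeric(k, n)
        calls_a = np.zeros(n, dtype=int)
        calls_b = np.r_[np.ones(k, dtype=int), np.zeros(n - k, dtype=int)]
        est = lk.two_point(_mk("a", calls_a), _mk("b", calls_b))
        assert est.theta == pytest.approx(theta_o, abs=1e-5)
        assert est.lod == pytest.approx(lod_o, abs=1e-4)

    def test_independent_vectors_near_half(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 1000)
        b = rng.integers(0, 2, 1000)
        est = lk.two_point(_mk("a", a), _mk("b", b))
        se = math.sqrt(0.25 / 1000)
        assert abs(est.theta - 0.5) <= 3 * se + 1e-12
        assert est.lod < 3.0

    def test_incompatible_classes_are_uninformative(self):
        est = lk.two_point(_mk("a", [0, 1] * 10, "maternal"),
                           _mk("b", [0, 1] * 10, "paternal"))
        assert not est.informative

    def test_too_few_shared_progeny(self):
        with pytest.raises(ValueError, match="shared informative"):
            lk.two_point(_mk("a", [0, 1, 0]), _mk("b", [1, 0, 1]), min_shared=10)

    def test_pairwise_agrees_with_scalar(self):
        rng = np.random.default_rng(3)
        g = pd.DataFrame(rng.integers(0, 2, (60, 5)).astype(float),
                         columns=list("abcde"))
        g.iloc[2, 0] = np.nan
        theta, lod, n = lk.pairwise_two_point(g)
        for i, m1 in enumerate(g.columns):
            for m2 in g.columns[i + 1:]:
                c1 = np.where(np.isnan(g[m1]), -1, g[m1]).astype(np.int8)
                c2 = np.where(np.isnan(g[m2]), -1, g[m2]).astype(np.int8)
                est = lk.two_point(_mk(m1, c1), _mk(m2, c2))
                assert theta.loc[m1, m2] == pytest.approx(est.theta)
                assert lod.loc[m1, m2] == pytest.approx(est.lod, abs=1e-9)


class TestDistortion:
    def test_balanced_not_distorted(self):
        chi2, _, flag = lk.segregation_distortion_test(np.array([0] * 50 + [1] * 50))
        assert chi2 == 0.0 and not flag

    def test_70_30_distorted(self):
        chi2, p, flag = lk.segregation_distortion_test(
            np.array([1] * 70 + [0] * 30), alpha=0.01)
        assert chi2 == pytest.approx(16.0)
        assert flag

    def test_degenerate_column_flagged_finite(self):
        chi2, _, flag = lk.segregation_distortion_test(np.array([0] * 100))
        assert np.isfinite(chi2) and flag

    def test_all_missing_is_error(self):
        with pytest.raises(ValueError):
            lk.segregation_distortion_test(np.array([-1, -1, -1]))


class TestGrouping:
    def _frames(self, markers, edges):
        theta = pd.DataFrame(np.nan, index=markers, columns=markers)
        lod = pd.DataFrame(0.0, index=markers, columns=markers)
        for a, b in edges:
            theta.loc[a, b] = theta.loc[b, a] = 0.1
            lod.loc[a, b] = lod.loc[b, a] = 10.0
        return theta, lod

    def test_chain_closes_transitively(self):
        markers = list("ABCDE")
        theta, lod = self._frames(markers, [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])
        groups = lk.group_markers(theta, lod)
        assert groups == [markers]

    def test_marker_without_edge_is_singleton(self):
        theta, lod = self._frames(list("ABC"), [("A", "B")])
        groups = lk.group_markers(theta, lod)
        assert ["C"] in groups

    def test_recovers_two_simulated_groups(self):
        cfg = sim.TrueMapConfig(n_groups=2, group_lengths=(50.0, 50.0),
                                markers_per_group=8, class_mix=(1.0, 0.0, 0.0), seed=5)
        tmap = sim.simulate_parents_and_map(cfg)
        geno = sim.simulate_progeny(tmap, 1000, 6, missing_rate=0.0)
        theta, lod, _ = lk.pairwise_two_point(geno.maternal)
        groups = [g for g in lk.group_markers(theta, lod) if len(g) > 1]
        truth = {g: set(sub["marker"]) for g, sub in tmap.groupby("group")}
        assert len(groups) == 2
        assert {frozenset(g) for g in groups} == {frozenset(v) for v in truth.values()}

    def test_invariant_to_marker_order(self):
        markers = list("ABCDEF")
        theta, lod = self._frames(markers, [("A", "B"), ("C", "D"), ("E", "F")])
        shuffled = ["E", "C", "A", "F", "B", "D"]
        g1 = lk.group_markers(theta, lod)
        g2 = lk.group_markers(theta.loc[shuffled, shuffled], lod.loc[shuffled, shuffled])
        assert g1 == g2


class TestOrdering:
    def test_additive_three_markers(self):
        theta = pd.DataFrame(
            [[0.0, 0.05, 0.10], [0.05, 0.0, 0.05], [0.10, 0.05, 0.0]],
            index=list("ABC"), columns=list("ABC"))
        order, pos = lk.order_group(list("ABC"), theta)
        assert order in (["A", "B", "C"], ["C", "B", "A"])
        assert pos[0] == 0.0 and np.all(np.diff(pos) > 0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_small_groups_match_exhaustive_oracle(self, seed):
        cfg = sim.TrueMapConfig(n_groups=1, group_lengths=(60.0,),
                                markers_per_group=7, class_mix=(1.0, 0.0, 0.0), seed=seed)
        tmap = sim.simulate_parents_and_map(cfg)
        geno = sim.simulate_progeny(tmap, 300, seed + 50, missing_rate=0.0)
        theta, lod, _ = lk.pairwise_two_point(geno.maternal)
        markers = list(theta.index)
        order, _ = lk.order_group(markers, theta)
        idx = [markers.index(m) for m in order]
        _, best_cost = best_order_exhaustive(theta.to_numpy())
        cost = sum(theta.to_numpy()[a, b] for a, b in zip(idx[:-1], idx[1:]))
        assert cost == pytest.approx(best_cost, abs=1e-12)

    def test_large_group_order_close_to_truth(self):
        from scipy.stats import kendalltau
        cfg = sim.TrueMapConfig(n_groups=1, group_lengths=(100.0,),
                                markers_per_group=20, class_mix=(1.0, 0.0, 0.0), seed=9)
        tmap = sim.simulate_parents_and_map(cfg)
        geno = sim.simulate_progeny(tmap, 500, 10, missing_rate=0.0)
        theta, _, _ = lk.pairwise_two_point(geno.maternal)
        order, _ = lk.order_group(list(theta.index), theta)
        true_pos = tmap.set_index("marker").loc[order, "position_cM"].to_numpy()
        tau = abs(kendalltau(true_pos, np.arange(len(order))).statistic)
        assert tau >= 0.9

    def test_map_length_invariant_under_reversal(self):
        cfg = sim.TrueMapConfig(n_groups=1, group_lengths=(80.0,),
                                markers_per_group=10, class_mix=(1.0, 0.0, 0.0), seed=4)
        tmap = sim.simulate_parents_and_map(cfg)
        geno = sim.simulate_progeny(tmap, 400, 11, missing_rate=0.0)
        theta, _, _ = lk.pairwise_two_point(geno.maternal)
        order, pos = lk.order_group(list(theta.index), theta)
        order_r, pos_r = lk.order_group(list(theta.index)[::-1], theta)
        assert pos[-1] == pytest.approx(pos_r[-1])


class TestMerge:
    def _spec(self, positions, markers=None, map_id="A"):
        markers = markers or [f"a{i}" for i in range(len(positions))]
        return LinkageMapSpec(map_id, "parental", pd.DataFrame(
            {"group": "I", "marker": markers, "position_cM": positions}))

    def test_idempotent_on_identical_maps(self):
        a = self._spec([0.0, 10.0, 30.0])
        b = self._spec([0.0, 10.0, 30.0], map_id="B")
        merged, _ = lk.merge_maps([a, b])
        assert np.allclose(merged.df["position_cM"], [0.0, 10.0, 30.0])

    def test_doubled_map_gives_mean_frame(self):
        a = self._spec([0.0, 10.0, 30.0])
        b = self._spec([0.0, 20.0, 60.0], map_id="B")
        merged, _ = lk.merge_maps([a, b])
        assert np.allclose(merged.df["position_cM"], [0.0, 15.0, 45.0])

    def test_symmetric_up_to_orientation(self):
        a = self._spec([0.0, 10.0, 30.0])
        b = self._spec([0.0, 20.0, 60.0], map_id="B")
        m1, _ = lk.merge_maps([a, b])
        m2, _ = lk.merge_maps([b, a])
        s1 = np.diff(np.sort(m1.df["position_cM"]))
        s2 = np.diff(np.sort(m2.df["position_cM"]))
        assert np.allclose(s1, s2) or np.allclose(s1, s2[::-1])

    def test_composite_order_matches_truth(self):
        cfg = sim.TrueMapConfig(n_groups=2, group_lengths=(100.0, 100.0),
                                markers_per_group=16, seed=7)
        tmap = sim.simulate_parents_and_map(cfg)
        geno = sim.simulate_progeny(tmap, 600, 8, missing_rate=0.0)
        seg = dict(zip(tmap["marker"], tmap["seg_class"]))
        mm, _ = lk.build_parental_map(geno.maternal, "mat", seg_classes=seg)
        pm, _ = lk.build_parental_map(geno.paternal, "pat", seg_classes=seg)
        merged, _ = lk.merge_maps([mm, pm])
        agree = total = 0
        truth_pos = tmap.set_index("marker")["position_cM"]
        truth_grp = tmap.set_index("marker")["group"]
        for grp in merged.groups:
            sub = merged.df[merged.df["group"] == grp]
            mk = [m for m in sub["marker"] if len(set(truth_grp[sub["marker"]])) == 1]
            tp = truth_pos[sub["marker"]].to_numpy()
            d = np.diff(tp)
            direction = np.sign(np.median(np.sign(d))) or 1.0
            agree += int(np.sum(np.sign(d) == direction))
            total += len(d)
        assert agree / total >= 0.95


class TestColinearity:
    def _spec(self, order, map_id="A"):
        return LinkageMapSpec(map_id, "parental", pd.DataFrame(
            {"group": "I", "marker": order,
             "position_cM": np.arange(len(order), dtype=float) * 10}))

    def test_identical_maps_100_percent(self):
        a = self._spec(list("abcdef"))
        b = self._spec(list("abcdef"), "B")
        st = lk.colinearity_stats(a, b)
        assert st == {"shared": 6, "same_order": 6, "percent": 100.0}

    def test_one_displaced_marker(self):
        a = self._spec(list("abcdef"))
        b = self._spec(["a", "c", "d", "b", "e", "f"], "B")
        st = lk.colinearity_stats(a, b)
        assert st["shared"] == 6 and st["same_order"] == 5
        assert st["percent"] == 83.3

    def test_reversed_group_still_colinear(self):
        a = self._spec(list("abcdef"))
        b = self._spec(list("fedcba"), "B")
        assert lk.colinearity_stats(a, b)["percent"] == 100.0

    def test_no_shared_markers(self):
        a = self._spec(list("abc"))
        b = self._spec(list("xyz"), "B")
        st = lk.colinearity_stats(a, b)
        assert st == {"shared": 0, "same_order": 0, "percent": 0.0}
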