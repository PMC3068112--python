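"""Homothetic projection, cluster consolidation and stability tabulation."""

import numpy as np
import pandas as pd
import pytest

from budqtl import experiments, project
from budqtl.linkage import LinkageMapSpec
from budqtl.scan import QtlRecord


def _frame(src, dst, span=(0.0, 100.0)):
    return project.AnchorFrame("I", [f"a{i}" for i in range(len(src))],
                               np.asarray(src, dtype=float),
                               np.asarray(dst, dtype=float), span)


def _record(peak=20.0, ci1=(15.0, 25.0), ci2=(10.0, 30.0), group="I", **kw):
    base = dict(dataset="d", trait="height", population="P", parent="maternal",
                site="VES", year=2004, pc=None, group=group, peak_cM=peak,
                lod=5.0, ppve_pct=8.0, effect=1.0, ci1=ci1, ci2=ci2,
                qtl_class="significant")
    base.update(kw)
    return QtlRecord(**base)


class TestProjectPosition:
    def test_anchor_fixed_points(self):
        fr = _frame([10.0, 30.0], [20.0, 60.0])
        assert project.project_position(10.0, fr) == 20.0
        assert project.project_position(30.0, fr) == 60.0

    def test_linear_midpoint(self):
        fr = _frame([10.0, 30.0], [20.0, 60.0])
        assert project.project_position(20.0, fr) == 40.0

    def test_round_trip_identity(self):
        fr = _frame([0.0, 25.0, 60.0], [0.0, 40.0, 90.0])
        inv = _frame([0.0, 40.0, 90.0], [0.0, 25.0, 60.0])
        for p in np.linspace(0.0, 60.0, 13):
            assert project.project_position(
                project.project_position(p, fr), inv) == pytest.approx(p, abs=1e-8)

    def test_extrapolation_capped_at_group_ends(self):
        fr = _frame([10.0, 30.0], [20.0, 60.0], span=(0.0, 70.0))
        assert project.project_position(40.0, fr) == 70.0  # would be 80 uncapped

    def test_needs_two_anchors(self):
        with pytest.raises(ValueError):
            project.AnchorFrame("I", ["a"], np.array([1.0]), np.array([1.0]), (0, 10))


class TestProjectQtl:
    def test_identity_frame_is_identity(self):
        fr = _frame([0.0, 100.0], [0.0, 100.0])
        out = project.project_qtl(_record(), fr)
        assert out["peak_cM"] == 20.0
        assert out["ci1"] == (15.0, 25.0) and out["ci2"] == (10.0, 30.0)

    def test_doubling_frame_doubles_width(self):
        fr = _frame([0.0, 100.0], [0.0, 200.0], span=(0.0, 200.0))
        out = project.project_qtl(_record(), fr)
        assert out["ci1"] == (30.0, 50.0)
        assert out["ci2"][1] - out["ci2"][0] == pytest.approx(40.0)

    def test_nesting_preserved(self):
        fr = _frame([0.0, 40.0, 100.0], [0.0, 70.0, 130.0], span=(0.0, 130.0))
        out = project.project_qtl(_record(), fr)
        assert out["ci2"][0] <= out["ci1"][0] <= out["peak_cM"] <= out["ci1"][1] <= out["ci2"][1]

    def test_unprojectable_group_reported(self):
        frames = {"II": _frame([0.0, 50.0], [0.0, 50.0])}
        projected, failed = project.project_records([_record(group="I")], frames)
        assert projected == [] and len(failed) == 1

    def test_simulated_projection_accuracy(self):
        rate = experiments.projection_accuracy(n_reps=20, seed=5)
        assert rate >= 0.9


def _proj(trait, group, lo, hi, dataset="d", population="P", year=2004, site="VES"):
    return {"dataset": dataset, "trait": trait, "population": population,
            "parent": "maternal", "site": site, "year": year, "pc": None,
            "source_group": group, "group": group, "peak_cM": (lo + hi) / 2,
            "lod": 5.0, "ppve_pct": 8.0, "qtl_class": "significant",
            "ci1": (lo, hi), "ci2": (lo - 5, hi + 5)}


def _composite(marker_positions):
    return LinkageMapSpec("comp", "composite", pd.DataFrame({
        "group": "I", "marker": [f"m{i}" for i in range(len(marker_positions))],
        "position_cM": marker_positions}))


class TestClusters:
    def test_overlap_with_shared_marker_joins(self):
        comp = _composite([0.0, 17.0, 40.0])
        clusters = project.consolidate_clusters(
            [_proj("height", "I", 10, 20), _proj("height", "I", 15, 25, dataset="e")],
            comp)
        assert len(clusters) == 1 and clusters[0].n_members == 2

    def test_overlap_without_marker_stays_apart(self):
        comp = _composite([0.0, 5.0, 40.0])  # nothing inside [15, 20]
        clusters = project.consolidate_clusters(
            [_proj("height", "I", 10, 20), _proj("height", "I", 15, 25, dataset="e")],
            comp)
        assert len(clusters) == 2

    def test_chain_closes_into_one_cluster(self):
        comp = _composite(np.arange(0.0, 60.0, 2.0))
        a = _proj("height", "I", 0, 12, dataset="a")
        b = _proj("height", "I", 10, 22, dataset="b")
        c = _proj("height", "I", 20, 32, dataset="c")  # c does not touch a
        clusters = project.consolidate_clusters([a, b, c], comp)
        assert len(clusters) == 1 and clusters[0].n_members == 3
        lo, hi = clusters[0].interval
        assert lo == 0 and hi == 32

    def test_invariant_to_input_order_and_counts_conserved(self):
        comp = _composite(np.arange(0.0, 60.0, 2.0))
        recs = [_proj("height", "I", 0, 12, dataset="a"),
                _proj("height", "I", 30, 40, dataset="b"),
                _proj("height", "I", 8, 20, dataset="c")]
        c1 = project.consolidate_clusters(recs, comp)
        c2 = project.consolidate_clusters(recs[::-1], comp)
        assert [c.n_members for c in c1] == [c.n_members for c in c2]
        assert sum(c.n_members for c in c1) == len(recs)
        assert len(c1) <= len(recs)

    def test_mixed_traits_rejected(self):
        comp = _composite([0.0, 10.0])
        with pytest.raises(ValueError):
            project.consolidate_clusters(
                [_proj("height", "I", 0, 5), _proj("bud_set", "I", 0, 5)], comp)


class TestStability:
    def _cluster(self, members):
        return project.QtlCluster(trait=members[0]["trait"],
                                  group=members[0]["group"], members=members)

    def test_20_percent_population_replication(self):
        comp_members = [
            [_proj("height", "I", 0, 10), _proj("height", "I", 2, 12, population="D")],
            [_proj("height", "I", 20, 30)],
            [_proj("height", "I", 40, 50)],
            [_proj("height", "I", 60, 70)],
            [_proj("height", "I", 80, 90)],
        ]
        tab = project.stability_table({"height": [self._cluster(m) for m in comp_members]})
        row = tab.iloc[0]
        assert row["n_clusters"] == 5
        assert row["pop_replicated"] == 1
        assert row["pop_replicated_pct"] == 20

    def test_single_member_cluster_no_flags(self):
        tab = project.stability_table({"height": [self._cluster([_proj("height", "I", 0, 10)])]})
        row = tab.iloc[0]
        assert row["pop_replicated"] == 0
        assert row["year_replicated"] == 0
        assert row["env_replicated"] == 0

    def test_indoor_specific_flagged(self):
        members = [_proj("height", "I", 0, 10, site="AAFC"),
                   _proj("height", "I", 2, 12, site="AAFC", year=2005)]
        tab = project.stability_table({"height": [self._cluster(members)]})
        assert tab.iloc[0]["indoor_specific"] == 1
        assert tab.iloc[0]["year_replicated"] == 1
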