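"""Projection of QTLs onto the composite map and cluster consolidation.

A QTL detected on a parental map is carried onto the composite map by a
homothetic (piecewise-linear) function anchored on markers shared by the
source map and the composite map: a position between two flanking anchors
is rescaled linearly between their composite positions.  Anchors whose
order disagrees between the two maps are skipped in favour of the next
flanking markers (a longest-increasing-subsequence filter).

Projected QTLs of one trait are consolidated into QTL clusters: two QTLs
belong together when their -1 LOD intervals overlap on the same composite
group AND the overlap contains at least one composite-map marker (shared
genomic region in the mapped-gene sense).  Clusters are the connected
components of that relation.  Stability tables count clusters replicated
across mapping populations, years and environments.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .linkage import LinkageMapSpec, longest_increasing_subsequence


# ---------------------------------------------------------------------------
# anchor frames
# ---------------------------------------------------------------------------

@dataclass
class AnchorFrame:
    """Shared-marker correspondence for one group of one source map."""

    group: str
    markers: list[str]
    source_pos: np.ndarray
    composite_pos: np.ndarray
    composite_span: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.markers) < 2:
            raise ValueError(f"group {self.group}: need >= 2 anchors to project")


def build_anchor_frames(
    source: LinkageMapSpec, composite: LinkageMapSpec
) -> dict[str, AnchorFrame]:
    """Anchor frames for every source group with >= 2 order-consistent anchors.

    Source groups are matched to the composite group holding most of their
    shared markers; order-discordant anchors are removed by an LIS filter so
    both position sequences are monotone (projection then automatically
    falls back to the next flanking markers).
    """
    comp = {m: (g, p) for g, m, p in zip(
        composite.df["group"], composite.df["marker"], composite.df["position_cM"])}
    frames: dict[str, AnchorFrame] = {}
    for grp in source.groups:
        posn = source.group_positions(grp).sort_values()
        shared = [(m, p, comp[m]) for m, p in posn.items() if m in comp]
        if len(shared) < 2:
            continue
        target = pd.Series([g for _, _, (g, _) in shared]).mode().iloc[0]
        shared = [(m, p, cp) for m, p, (g, cp) in shared if g == target]
        if len(shared) < 2:
            continue
        cpos = [cp for _, _, cp in shared]
        inc = longest_increasing_subsequence(cpos)
        dec = longest_increasing_subsequence([-x for x in cpos])
        keep = inc if len(inc) >= len(dec) else dec
        if len(keep) < len(shared):
            dropped = [shared[i][0] for i in range(len(shared)) if i not in set(keep)]
            _warnings.warn(f"group {grp}: order-discordant anchors skipped: {dropped}")
        kept = [shared[i] for i in keep]
        if len(kept) < 2:
            continue
        allpos = composite.df.loc[composite.df["group"] == target, "position_cM"]
        frames[grp] = AnchorFrame(
            group=target,
            markers=[m for m, _, _ in kept],
            source_pos=np.array([p for _, p, _ in kept], dtype=float),
            composite_pos=np.array([cp for _, _, cp in kept], dtype=float),
            composite_span=(float(allpos.min()), float(allpos.max())),
        )
    return frames


def project_position(pos: float, frame: AnchorFrame) -> float:
    """Homothetic projection of a source-map position to the composite map.

    Between flanking anchors (aL -> AL, aR -> AR):
    P = AL + (pos - aL) * (AR - AL) / (aR - aL).  Positions beyond the
    terminal anchors extrapolate with the terminal pair's ratio, capped at
    the composite group ends.
    """
    s, c = frame.source_pos, frame.composite_pos
    flip = s[-1] < s[0]
    if flip:
        s, c = s[::-1], c[::-1]
    j = int(np.clip(np.searchsorted(s, pos) - 1, 0, len(s) - 2))
    aL, aR = s[j], s[j + 1]
    AL, AR = c[j], c[j + 1]
    if aR == aL:
        proj = AL
    else:
        proj = AL + (pos - aL) * (AR - AL) / (aR - aL)
    lo, hi = frame.composite_span
    return float(np.clip(proj, lo, hi))


def project_qtl(record, frame: AnchorFrame) -> dict:
    """Project a QtlRecord's peak and both support intervals.

    Endpoints are projected independently; if the projected interval comes
    out inverted (fallback anchors), it is swapped with a warning.  Returns
    a plain record dict on the composite frame.
    """
    peak = project_position(record.peak_cM, frame)
    out = {
        "dataset": record.dataset, "trait": record.trait,
        "population": record.population, "parent": record.parent,
        "site": record.site, "year": record.year, "pc": record.pc,
        "source_group": record.group, "group": frame.group,
        "peak_cM": round(peak, 1), "lod": record.lod,
        "ppve_pct": record.ppve_pct, "qtl_class": record.qtl_class,
    }
    for name, (lo, hi) in (("ci1", record.ci1), ("ci2", record.ci2)):
        a, b = project_position(lo, frame), project_position(hi, frame)
        if a > b:
            _warnings.warn(f"{record.dataset}: projected {name} inverted; endpoints swapped")
            a, b = b, a
        out[name] = (round(min(a, peak), 1), round(max(b, peak), 1))
    return out


def project_records(records, frames: dict[str, AnchorFrame]) -> tuple[list[dict], list]:
    """Project a batch of QtlRecords; unprojectable ones are returned apart."""
    projected, failed = [], []
    for rec in records:
        frame = frames.get(rec.group)
        if frame is None:
            failed.append(rec)
            continue
        projected.append(project_qtl(rec, frame))
    return projected, failed


# ---------------------------------------------------------------------------
# cluster consolidation
# ---------------------------------------------------------------------------

@dataclass
class QtlCluster:
    trait: str
    group: str
    members: list[dict] = field(repr=False)
    interval: tuple[float, float] = (np.nan, np.nan)

    def __post_init__(self) -> None:
        los = [m["ci1"][0] for m in self.members]
        his = [m["ci1"][1] for m in self.members]
        self.interval = (float(min(los)), float(max(his)))

    @property
    def populations(self) -> set[str]:
        return {m["population"] for m in self.members}

    @property
    def years(self) -> set[int]:
        return {int(m["year"]) for m in self.members}

    @property
    def sites(self) -> set[str]:
        return {m["site"] for m in self.members}

    @property
    def n_members(self) -> int:
        return len(self.members)


def consolidate_clusters(
    projected: list[dict], composite: LinkageMapSpec
) -> list[QtlCluster]:
    """Group projected QTLs of one trait into composite-map clusters.

    Two QTLs are linked when their -1 LOD intervals overlap (closed) on the
    same group and the overlap contains at least one composite-map marker;
    clusters are connected components, ordered by group then position.
    """
    traits = {r["trait"] for r in projected}
    if len(traits) > 1:
        raise ValueError("consolidate one trait at a time")
    marker_pos = {
        g: composite.df.loc[composite.df["group"] == g, "position_cM"].to_numpy()
        for g in composite.groups
    }
    graph = nx.Graph()
    graph.add_nodes_from(range(len(projected)))
    for i in range(len(projected)):
        for j in range(i + 1, len(projected)):
            a, b = projected[i], projected[j]
            if a["group"] != b["group"]:
                continue
            lo = max(a["ci1"][0], b["ci1"][0])
            hi = min(a["ci1"][1], b["ci1"][1])
            if lo > hi:
                continue
            mpos = marker_pos.get(a["group"], np.array([]))
            if np.any((mpos >= lo) & (mpos <= hi)):
                graph.add_edge(i, j)
    clusters = []
    for comp in nx.connected_components(graph):
        members = sorted((projected[i] for i in comp),
                         key=lambda r: (r["group"], r["peak_cM"], r["dataset"]))
        clusters.append(QtlCluster(trait=members[0]["trait"],
                                   group=members[0]["group"], members=members))
    clusters.sort(key=lambda c: (c.group, c.interval[0], c.interval[1]))
    return clusters


# ---------------------------------------------------------------------------
# stability tabulation
# ---------------------------------------------------------------------------

def stability_table(clusters_by_trait: dict[str, list[QtlCluster]]) -> pd.DataFrame:
    """Replication of QTL clusters across populations, years and environments.

    A cluster is population-replicated when its members span both mapping
    populations, year-replicated when members span >= 2 years within a
    population, environment-replicated when members span both block
    environments (VES outdoor / AAFC indoor).  Context-specific counts
    record clusters confined to a single environment.  Percentages are on
    cluster counts per trait, rounded to integer (half-up).
    """
    from .report import round_half_up

    rows = []
    for trait, clusters in clusters_by_trait.items():
        n = len(clusters)
        pop_rep = sum(1 for c in clusters if len(c.populations) >= 2)
        year_rep = 0
        for c in clusters:
            by_pop: dict[str, set[int]] = {}
            for m in c.members:
                by_pop.setdefault(m["population"], set()).add(int(m["year"]))
            if any(len(v) >= 2 for v in by_pop.values()):
                year_rep += 1
        env_rep = sum(1 for c in clusters if {"VES", "AAFC"} <= c.sites)
        indoor_only = sum(1 for c in clusters if c.sites == {"AAFC"})
        outdoor_only = sum(1 for c in clusters if c.sites == {"VES"})
        rows.append({
            "trait": trait,
            "n_clusters": n,
            "pop_replicated": pop_rep,
            "pop_replicated_pct": round_half_up(100.0 * pop_rep / n) if n else 0,
            "year_replicated": year_rep,
            "year_replicated_pct": round_half_up(100.0 * year_rep / n) if n else 0,
            "env_replicated": env_rep,
            "env_replicated_pct": round_half_up(100.0 * env_rep / n) if n else 0,
            "indoor_specific": indoor_only,
            "outdoor_specific": outdoor_only,
        })
    return pd.DataFrame(rows)


def clusters_to_frame(clusters_by_trait: dict[str, list[QtlCluster]]) -> pd.DataFrame:
    """Flat cluster table (one row per cluster) for TSV output."""
    rows = []
    for trait, clusters in clusters_by_trait.items():
        for i, c in enumerate(clusters, start=1):
            rows.append({
                "trait": trait,
                "cluster": f"{trait}_{c.group}_{i}",
                "group": c.group,
                "interval_lo": round(c.interval[0], 1),
                "interval_hi": round(c.interval[1], 1),
                "n_members": c.n_members,
                "members": ";".join(m["dataset"] + "@" + m["source_group"] for m in c.members),
                "pop_P": "P" in c.populations,
                "pop_D": "D" in c.populations,
                "years": ";".join(str(y) for y in sorted(c.years)),
                "VES": "VES" in c.sites,
                "AAFC": "AAFC" in c.sites,
            })
    return pd.DataFrame(rows)
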