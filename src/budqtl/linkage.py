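"""Pseudo-testcross linkage map construction.

Markers that are heterozygous in one parent and homozygous in the other
segregate 1:1 in a full-sib family and can be mapped as a backcross on that
parent ("two-way pseudo-testcross").  Fully informative anchor markers are
heterozygous in both parents and contribute a 1:1 column to each parental
map, which is what later allows parental maps to be merged.

The module covers two-point estimation of recombination fractions, the
Kosambi map function, a chi-square filter for segregation distortion,
LOD/theta grouping, SARF marker ordering (exhaustive for small groups,
greedy + 2-opt otherwise), merging of maps through shared anchors, and
colinearity statistics between maps.
"""

from __future__ import annotations

import itertools
import math
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1
LOG10_2 = math.log10(2.0)

MATERNAL = "maternal"
PATERNAL = "paternal"
ANCHOR = "anchor"

_ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII",
    "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX",
]


def roman(i: int) -> str:
    """1-based linkage group numeral (I, II, ... as printed on conifer maps)."""
    if 1 <= i <= len(_ROMAN):
        return _ROMAN[i - 1]
    return f"G{i}"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MarkerGenotypes:
    """One marker's coded calls across progeny.

    ``calls`` holds allele-origin codes {0, 1} for the informative parent,
    with -1 for missing.  ``seg_class`` is 'maternal', 'paternal' or 'anchor'.
    """

    marker: str
    seg_class: str
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise ValueError(f"marker {self.marker}: codes must be 0/1/missing")


@dataclass
class TwoPointEstimate:
    marker1: str
    marker2: str
    theta: float
    lod: float
    n_informative: int
    informative: bool = True


@dataclass
class LinkageMapSpec:
    """Ordered markers with Kosambi cM positions, one frame per group."""

    map_id: str
    kind: str  # 'parental' | 'sub-composite' | 'composite'
    df: pd.DataFrame = field(repr=False)  # columns: group, marker, position_cM

    def __post_init__(self) -> None:
        req = {"group", "marker", "position_cM"}
        if not req.issubset(self.df.columns):
            raise ValueError(f"map table needs columns {sorted(req)}")
        self.df = self.df.sort_values(["group", "position_cM", "marker"]).reset_index(drop=True)

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.df["group"]))

    def group_positions(self, group: str) -> pd.Series:
        sub = self.df[self.df["group"] == group]
        return pd.Series(sub["position_cM"].to_numpy(), index=sub["marker"].to_numpy())

    def group_length(self, group: str) -> float:
        pos = self.df.loc[self.df["group"] == group, "position_cM"]
        return float(pos.max() - pos.min()) if len(pos) else 0.0

    @property
    def total_length(self) -> float:
        return float(sum(self.group_length(g) for g in self.groups))

    @property
    def n_markers(self) -> int:
        return int(len(self.df))


# ---------------------------------------------------------------------------
# map function
# ---------------------------------------------------------------------------

def kosambi_cm(theta: float | np.ndarray) -> float | np.ndarray:
    """Kosambi map distance d = 25*ln((1+2t)/(1-2t)) in cM; inf at t >= 0.5."""
    t = np.asarray(theta, dtype=float)
    if np.any(t < 0) or np.any(t > 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    with np.errstate(divide="ignore"):
        d = 25.0 * np.log((1.0 + 2.0 * t) / (1.0 - 2.0 * t))
    return float(d) if np.isscalar(theta) else d


def inverse_kosambi(d: float | np.ndarray) -> float | np.ndarray:
    """Exact inverse of :func:`kosambi_cm`: theta = tanh(d/50)/2."""
    dd = np.asarray(d, dtype=float)
    if np.any(dd < 0):
        raise ValueError("map distance must be non-negative")
    t = 0.5 * np.tanh(dd / 50.0)
    return float(t) if np.isscalar(d) else t


# ---------------------------------------------------------------------------
# two-point estimation
# ---------------------------------------------------------------------------

def _testcross_lod(k: int, n: int) -> tuple[float, float]:
    """MLE theta and LOD for k apparent recombinants among n gametes."""
    theta = k / n
    if theta >= 0.5:
        return 0.5, 0.0
    lod = n * LOG10_2
    if k > 0:
        lod += k * math.log10(theta)
    if n - k > 0:
        lod += (n - k) * math.log10(1.0 - theta)
    return theta, lod


def two_point(m1: MarkerGenotypes, m2: MarkerGenotypes, min_shared: int = 10) -> TwoPointEstimate:
    """Two-point recombination estimate between two same-parent markers.

    Linkage phase is unknown in an outbred cross, so the recombinant count is
    taken as the smaller of the two phase interpretations.  Pairs informative
    in different parents (neither being an anchor) are returned as typed
    uninformative results.
    """
    compatible = (
        m1.seg_class == m2.seg_class
        or ANCHOR in (m1.seg_class, m2.seg_class)
    )
    if not compatible:
        return TwoPointEstimate(m1.marker, m2.marker, 0.5, 0.0, 0, informative=False)
    ok = (m1.calls != MISSING) & (m2.calls != MISSING)
    n = int(ok.sum())
    if n < min_shared:
        raise ValueError(
            f"pair {m1.marker}/{m2.marker}: only {n} shared informative progeny (< {min_shared})"
        )
    diff = int((m1.calls[ok] != m2.calls[ok]).sum())
    k = min(diff, n - diff)  # phase-minimised recombinant count
    theta, lod = _testcross_lod(k, n)
    return TwoPointEstimate(m1.marker, m2.marker, theta, lod, n)


def pairwise_two_point(
    genotypes: pd.DataFrame, min_shared: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All-pairs two-point estimates for one parent's marker table.

    ``genotypes``: progeny x marker frame with values in {0, 1, NaN}.
    Returns (theta, lod, n) square frames indexed by marker.  Pairs with
    fewer than ``min_shared`` shared progeny get theta = NaN, LOD = 0.
    """
    markers = list(genotypes.columns)
    g = genotypes.to_numpy(dtype=float).T  # m x n
    valid = ~np.isnan(g)
    one = np.where(valid, g, 0.0) == 1.0
    zero = valid & ~one
    onef = one.astype(float)
    zerof = zero.astype(float)
    n = valid.astype(float) @ valid.astype(float).T
    diff = onef @ zerof.T + zerof @ onef.T
    k = np.minimum(diff, n - diff)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(n > 0, k / n, np.nan)
        lod = n * LOG10_2
        lod += np.where(k > 0, k * np.log10(np.where(k > 0, theta, 1.0)), 0.0)
        lod += np.where(
            n - k > 0, (n - k) * np.log10(np.where(theta < 1, 1.0 - theta, 1.0)), 0.0
        )
    lod = np.where(theta >= 0.5, 0.0, lod)
    small = n < min_shared
    theta[small] = np.nan
    lod[small] = 0.0
    np.fill_diagonal(theta, 0.0)
    np.fill_diagonal(lod, 0.0)
    idx = pd.Index(markers, name="marker")
    return (
        pd.DataFrame(theta, index=idx, columns=idx),
        pd.DataFrame(lod, index=idx, columns=idx),
        pd.DataFrame(n.astype(int), index=idx, columns=idx),
    )


# ---------------------------------------------------------------------------
# segregation distortion
# ---------------------------------------------------------------------------

def segregation_distortion_test(
    calls: np.ndarray | MarkerGenotypes, alpha: float = 0.01
) -> tuple[float, float, bool]:
    """Chi-square test of 1:1 segregation (df = 1) on a testcross marker.

    Returns (chi2, p, distorted).  All-missing input is an error.
    """
    if isinstance(calls, MarkerGenotypes):
        calls = calls.calls
    calls = np.asarray(calls)
    obs = calls[calls != MISSING]
    n = obs.size
    if n == 0:
        raise ValueError("marker has no scored progeny")
    n1 = int((obs == 1).sum())
    exp = n / 2.0
    chi2 = (n1 - exp) ** 2 / exp + ((n - n1) - exp) ** 2 / exp
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p, p < alpha


# ---------------------------------------------------------------------------
# grouping and ordering
# ---------------------------------------------------------------------------

def group_markers(
    theta: pd.DataFrame,
    lod: pd.DataFrame,
    lod_min: float = 6.0,
    theta_max: float = 0.35,
) -> list[list[str]]:
    """Linkage groups = connected components of the LOD/theta graph.

    An edge joins two markers when LOD >= lod_min AND theta <= theta_max.
    Components are returned sorted by their smallest marker id; singletons
    (unlinked markers) are included as one-element groups.
    """
    markers = list(theta.index)
    g = nx.Graph()
    g.add_nodes_from(markers)
    th = theta.to_numpy()
    lo = lod.to_numpy()
    edge = (lo >= lod_min) & (th <= theta_max) & ~np.isnan(th)
    ii, jj = np.where(np.triu(edge, k=1))
    g.add_edges_from((markers[i], markers[j]) for i, j in zip(ii, jj))
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    return comps


def _sarf(order: Sequence[int], th: np.ndarray) -> float:
    total = 0.0
    for a, b in zip(order[:-1], order[1:]):
        t = th[a, b]
        total += 0.5 if np.isnan(t) else t
    return total


def _greedy_path(th: np.ndarray) -> list[int]:
    m = th.shape[0]
    t = np.where(np.isnan(th), 0.5, th).copy()
    np.fill_diagonal(t, np.inf)
    a, b = np.unravel_index(np.argmin(t), t.shape)
    path = [int(a), int(b)]
    used = {int(a), int(b)}
    while len(path) < m:
        best = None
        for end, insert_front in ((path[0], True), (path[-1], False)):
            for cand in range(m):
                if cand in used:
                    continue
                c = t[end, cand]
                if best is None or c < best[0]:
                    best = (c, cand, insert_front)
        _, cand, front = best
        used.add(cand)
        if front:
            path.insert(0, cand)
        else:
            path.append(cand)
    return path


def _two_opt(order: list[int], th: np.ndarray, max_rounds: int = 40) -> list[int]:
    m = len(order)
    best = list(order)
    best_cost = _sarf(best, th)
    for _ in range(max_rounds):
        improved = False
        for i in range(m - 1):
            for j in range(i + 1, m):
                cand = best[:i] + best[i : j + 1][::-1] + best[j + 1 :]
                cost = _sarf(cand, th)
                if cost < best_cost - 1e-12:
                    best, best_cost = cand, cost
                    improved = True
        if not improved:
            break
    return best


def order_group(
    markers: Sequence[str],
    theta: pd.DataFrame,
    exhaustive_limit: int = 7,
) -> tuple[list[str], np.ndarray]:
    """Order one linkage group's markers and assign cumulative Kosambi positions.

    The objective is the sum of adjacent recombination fractions (SARF);
    groups of up to ``exhaustive_limit`` markers are solved exactly by
    enumeration, larger ones by greedy nearest-neighbour seeding plus 2-opt.
    Positions start at 0.  Ties between a path and its reverse are broken so
    the lexicographically smaller terminal marker comes first.
    """
    markers = list(markers)
    if len(markers) < 2:
        return markers, np.zeros(len(markers))
    th = theta.loc[markers, markers].to_numpy()
    m = len(markers)
    if np.isnan(th[np.triu_indices(m, 1)]).all() and m > 1:
        raise ValueError("no informative two-point estimates within the group")
    if m <= exhaustive_limit:
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(m)):
            if perm[0] > perm[-1]:
                continue  # each order and its reverse have the same SARF
            cost = _sarf(perm, th)
            if cost < best_cost - 1e-12:
                best, best_cost = list(perm), cost
    else:
        best = _two_opt(_greedy_path(th), th)
    if markers[best[-1]] < markers[best[0]]:
        best = best[::-1]
    adj = np.array([min(0.4999, th[a, b]) if not np.isnan(th[a, b]) else 0.4999
                    for a, b in zip(best[:-1], best[1:])])
    pos = np.concatenate([[0.0], np.cumsum(kosambi_cm(adj))])
    return [markers[i] for i in best], pos


def build_parental_map(
    genotypes: pd.DataFrame,
    map_id: str,
    seg_classes: dict[str, str] | None = None,
    lod_min: float = 6.0,
    theta_max: float = 0.35,
    distortion_alpha: float = 0.01,
    min_shared: int = 10,
) -> tuple[LinkageMapSpec, dict]:
    """Assemble one parental map from a progeny x marker 0/1/NaN table.

    Distorted markers (chi-square 1:1 test at ``distortion_alpha``) are
    removed before grouping; markers with no qualifying linkage edge are
    reported unlinked.  Groups are numbered by decreasing marker count and
    oriented so that the lexicographically smallest anchor (or marker) id is
    nearer position 0.  Returns the map plus an assembly report.
    """
    seg_classes = seg_classes or {}
    distorted = []
    kept = []
    for mk in genotypes.columns:
        col = genotypes[mk].to_numpy(dtype=float)
        calls = np.where(np.isnan(col), MISSING, col).astype(np.int8)
        _, _, bad = segregation_distortion_test(calls, alpha=distortion_alpha)
        (distorted if bad else kept).append(mk)
    theta, lod, _ = pairwise_two_point(genotypes[kept], min_shared=min_shared)
    comps = group_markers(theta, lod, lod_min=lod_min, theta_max=theta_max)
    unlinked = [c[0] for c in comps if len(c) == 1]
    groups = [c for c in comps if len(c) >= 2]
    groups.sort(key=lambda c: (-len(c), c[0]))
    rows = []
    for gi, comp in enumerate(groups, start=1):
        ordered, pos = order_group(comp, theta)
        ordered, pos = orient_group(ordered, pos, seg_classes)
        for mk, p in zip(ordered, pos):
            rows.append({"group": roman(gi), "marker": mk, "position_cM": round(float(p), 4)})
    spec = LinkageMapSpec(map_id, "parental", pd.DataFrame(rows, columns=["group", "marker", "position_cM"]))
    report = {
        "available": int(genotypes.shape[1]),
        "distorted": distorted,
        "unlinked": unlinked,
        "positioned": len(rows),
        "n_groups": len(groups),
    }
    return spec, report


def orient_group(
    ordered: list[str], pos: np.ndarray, seg_classes: dict[str, str]
) -> tuple[list[str], np.ndarray]:
    """Orient a group so the smallest anchor id (fallback: marker id) is near 0."""
    anchors = [m for m in ordered if seg_classes.get(m) == ANCHOR]
    ref = min(anchors) if anchors else min(ordered)
    i = ordered.index(ref)
    span = pos[-1]
    if pos[i] > span - pos[i]:
        ordered = ordered[::-1]
        pos = span - pos[::-1]
    return ordered, pos


# ---------------------------------------------------------------------------
# map merging
# ---------------------------------------------------------------------------

def longest_increasing_subsequence(seq: Sequence[float]) -> list[int]:
    """Indices of one longest strictly increasing subsequence of ``seq``."""
    tails: list[float] = []
    tails_idx: list[int] = []
    prev = [-1] * len(seq)
    for i, x in enumerate(seq):
        j = bisect_left(tails, x)
        if j == len(tails):
            tails.append(x)
            tails_idx.append(i)
        else:
            tails[j] = x
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    out = []
    i = tails_idx[-1] if tails_idx else -1
    while i >= 0:
        out.append(i)
        i = prev[i]
    return out[::-1]


def _match_groups(ref: LinkageMapSpec, other: LinkageMapSpec) -> dict[str, str]:
    """Map each group of ``other`` to the ref group sharing most markers."""
    ref_of = {m: g for g, m in zip(ref.df["group"], ref.df["marker"])}
    match: dict[str, str] = {}
    for g in other.groups:
        shared = other.df.loc[other.df["group"] == g, "marker"].map(ref_of).dropna()
        if len(shared):
            match[g] = shared.mode().iloc[0]
    return match


def merge_maps(
    maps: Sequence[LinkageMapSpec],
    map_id: str = "composite",
    kind: str = "composite",
) -> tuple[LinkageMapSpec, dict]:
    """Merge maps through their shared (anchor) markers.

    Per group: each map is oriented against the first map, translated so the
    shared-anchor centroids coincide, order-discordant anchors are dropped by
    a longest-increasing-subsequence filter, and each anchor's merged
    position is the mean of its per-map positions.  Non-anchor markers are
    then placed by homothetic interpolation between their flanking anchors.
    Groups with fewer than two usable anchors are left unmerged and reported.
    """
    if len(maps) < 2:
        raise ValueError("need at least two maps to merge")
    ref = maps[0]
    counts: dict[str, int] = {}
    for mp in maps:
        for m in mp.df["marker"]:
            counts[m] = counts.get(m, 0) + 1
    anchors = {m for m, c in counts.items() if c >= 2}
    warnings: list[str] = []
    unmerged: list[str] = []
    rows = []
    for gi, rg in enumerate(ref.groups, start=1):
        # collect per-map coordinate frames for this group
        frames: list[pd.Series] = [ref.group_positions(rg)]
        for mp in maps[1:]:
            match = _match_groups(ref, mp)
            for og, tg in match.items():
                if tg == rg:
                    frames.append(mp.group_positions(og))
        # orientation + translation against the reference frame
        refpos = frames[0]
        aligned: list[pd.Series] = [refpos]
        for fr in frames[1:]:
            shared = [m for m in fr.index if m in refpos.index]
            if len(shared) < 2:
                unmerged.append(rg)
                warnings.append(f"group {rg}: a map had < 2 shared anchors; left out")
                continue
            a = refpos[shared].to_numpy()
            b = fr[shared].to_numpy()
            if np.corrcoef(a, b)[0, 1] < 0:
                fr = fr.max() - fr
                b = fr[shared].to_numpy()
            fr = fr + (a.mean() - b.mean())
            aligned.append(fr)
        # consensus anchor positions (means), LIS conflict removal per map
        anchor_pos: dict[str, list[float]] = {}
        order_ref = [m for m in refpos.sort_values().index if m in anchors]
        for fr in aligned:
            seq = [m for m in order_ref if m in fr.index]
            vals = [fr[m] for m in seq]
            keep = set(longest_increasing_subsequence(vals))
            for i, m in enumerate(seq):
                if i in keep:
                    anchor_pos.setdefault(m, []).append(float(fr[m]))
                else:
                    warnings.append(f"group {rg}: anchor {m} order-discordant in one map; skipped")
        consensus = {m: float(np.mean(v)) for m, v in anchor_pos.items()}
        if len(consensus) < 2:
            unmerged.append(rg)
            for mk, p in refpos.items():
                rows.append({"group": roman(gi), "marker": mk, "position_cM": float(p)})
            continue
        placed: dict[str, float] = dict(consensus)
        # homothetic placement of non-anchor markers from each source frame
        for fr in aligned:
            anc = sorted((p, m) for m, p in fr.items() if m in consensus)
            if len(anc) < 2:
                continue
            apos = np.array([p for p, _ in anc])
            for mk, p in fr.items():
                if mk in placed:
                    continue
                j = int(np.clip(np.searchsorted(apos, p) - 1, 0, len(anc) - 2))
                (aL, mL), (aR, mR) = anc[j], anc[j + 1]
                AL, AR = consensus[mL], consensus[mR]
                if aR == aL:
                    proj = AL
                else:
                    proj = AL + (p - aL) * (AR - AL) / (aR - aL)
                placed[mk] = float(proj)
        base = min(placed.values())
        for mk, p in sorted(placed.items(), key=lambda kv: (kv[1], kv[0])):
            rows.append({"group": roman(gi), "marker": mk, "position_cM": round(p - base, 4)})
    spec = LinkageMapSpec(map_id, kind, pd.DataFrame(rows, columns=["group", "marker", "position_cM"]))
    report = {"warnings": warnings, "unmerged_groups": sorted(set(unmerged)),
              "n_anchors": len(anchors & set(spec.df["marker"]))}
    return spec, report


# ---------------------------------------------------------------------------
# colinearity
# ---------------------------------------------------------------------------

def colinearity_stats(map_a: LinkageMapSpec, map_b: LinkageMapSpec) -> dict:
    """Shared-marker order agreement between two maps.

    Per matched group, the same-order count is the longest common monotone
    subsequence (either direction) of shared markers; the percentage is
    rounded to one decimal.  No shared markers is a zero-shared result.
    """
    pos_b = {m: (g, p) for g, m, p in zip(map_b.df["group"], map_b.df["marker"], map_b.df["position_cM"])}
    shared_total = 0
    same_total = 0
    for g in map_a.groups:
        sub = map_a.df[map_a.df["group"] == g].sort_values("position_cM")
        shared = [(m, pos_b[m]) for m in sub["marker"] if m in pos_b]
        if not shared:
            continue
        groups_b = pd.Series([gb for _, (gb, _) in shared])
        gb = groups_b.mode().iloc[0]
        seq = [p for _, (g2, p) in shared if g2 == gb]
        skipped = len(shared) - len(seq)
        shared_total += len(shared)
        if len(seq) >= 1:
            inc = len(longest_increasing_subsequence(seq))
            dec = len(longest_increasing_subsequence([-x for x in seq]))
            same_total += max(inc, dec)
        _ = skipped  # markers mapping to another group count as out of order
    pct = round(100.0 * same_total / shared_total, 1) if shared_total else 0.0
    return {"shared": shared_total, "same_order": same_total, "percent": pct}
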