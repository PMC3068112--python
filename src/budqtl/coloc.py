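"""Permutation test for QTL co-location between two traits.

The observed statistic is the proportion of QTL confidence intervals (of
either trait) that overlap at least one interval of the other trait on the
same composite linkage group.  Its null distribution is obtained by
re-placing every interval at random across the linkage map (group drawn
with probability proportional to group length among groups long enough to
hold it, start uniform on the feasible range, length preserved) and
recomputing the proportion, 1,000 times by default.  Co-location is deemed
significant when the observed proportion beats the randomized one at least
95% of the time; the add-one (Davison-Hinkley) estimator avoids zero
p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .linkage import LinkageMapSpec


@dataclass
class ColocationResult:
    trait_pair: tuple[str, str]
    observed: float
    null: np.ndarray = field(repr=False)
    exceedance: float = field(init=False)
    one_minus_p: float = field(init=False)
    significant: bool = field(init=False)
    seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.null)
        self.exceedance = float((np.sum(self.null >= self.observed) + 1) / (n + 1))
        self.one_minus_p = 1.0 - self.exceedance
        self.significant = self.exceedance < 0.05


def overlap_proportion(
    intervals_a: list[tuple[str, float, float]],
    intervals_b: list[tuple[str, float, float]],
) -> float:
    """Share of intervals (both traits pooled) overlapping the other trait.

    Intervals are (group, lo, hi), closed; overlap requires the same group.
    Either set empty is a no-test condition (ValueError).
    """
    if not intervals_a or not intervals_b:
        raise ValueError("no-test: at least one trait has no intervals")
    hits = 0
    for side, other in ((intervals_a, intervals_b), (intervals_b, intervals_a)):
        for g, lo, hi in side:
            if any(g == g2 and lo <= hi2 and lo2 <= hi for g2, lo2, hi2 in other):
                hits += 1
    return hits / (len(intervals_a) + len(intervals_b))


def _group_lengths(composite: LinkageMapSpec) -> tuple[list[str], np.ndarray]:
    groups = composite.groups
    return groups, np.array([composite.group_length(g) for g in groups])


def randomize_intervals(
    composite: LinkageMapSpec,
    intervals_a: list[tuple[str, float, float]],
    intervals_b: list[tuple[str, float, float]],
    n: int = 1000,
    seed: int = 0,
    within_group: bool = False,
) -> np.ndarray:
    """Null distribution of the overlap proportion under random placement.

    Every replicate independently re-places every interval of both traits,
    preserving its length.  Genome-wide placement draws the group with
    probability proportional to group length among the groups that can hold
    the interval; ``within_group=True`` instead keeps each interval on its
    original group.  An interval longer than every group is an error.
    """
    groups, lengths = _group_lengths(composite)
    gindex = {g: i for i, g in enumerate(groups)}
    all_iv = [(g, hi - lo) for g, lo, hi in intervals_a + intervals_b]
    n_a = len(intervals_a)
    rng = np.random.default_rng(seed)

    placed_group = np.empty((n, len(all_iv)), dtype=int)
    placed_lo = np.empty((n, len(all_iv)))
    for k, (g, w) in enumerate(all_iv):
        if within_group:
            gi = gindex[g]
            if lengths[gi] < w:
                raise ValueError(f"interval {k} ({w:.1f} cM) exceeds its group length")
            placed_group[:, k] = gi
            placed_lo[:, k] = rng.uniform(0.0, lengths[gi] - w, size=n)
        else:
            feasible = np.nonzero(lengths >= w)[0]
            if feasible.size == 0:
                raise ValueError(f"interval {k} ({w:.1f} cM) is longer than every group")
            p = lengths[feasible] / lengths[feasible].sum()
            gi = rng.choice(feasible, size=n, p=p)
            placed_group[:, k] = gi
            placed_lo[:, k] = rng.uniform(0.0, lengths[gi] - w, size=n)
    widths = np.array([w for _, w in all_iv])
    placed_hi = placed_lo + widths[None, :]

    # closed-interval overlap, same group, trait A columns vs trait B columns
    ga = placed_group[:, :n_a][:, :, None]
    gb = placed_group[:, n_a:][:, None, :]
    loa = placed_lo[:, :n_a][:, :, None]
    hia = placed_hi[:, :n_a][:, :, None]
    lob = placed_lo[:, n_a:][:, None, :]
    hib = placed_hi[:, n_a:][:, None, :]
    ov = (ga == gb) & (loa <= hib) & (lob <= hia)
    hits = ov.any(axis=2).sum(axis=1) + ov.any(axis=1).sum(axis=1)
    return hits / len(all_iv)


def colocation_significance(
    observed: float, null: np.ndarray, trait_pair: tuple[str, str] = ("A", "B"),
    seed: int | None = None,
) -> ColocationResult:
    """Empirical exceedance of the observed overlap against its null.

    exceedance = (# null >= observed + 1) / (n + 1); significant when
    exceedance < 0.05.  ``one_minus_p`` is the quantity quoted as the
    '1 - P-value' of the co-location.
    """
    null = np.asarray(null, dtype=float)
    if len(null) < 100:
        raise ValueError("need >= 100 null replicates (1,000 for reporting)")
    return ColocationResult(trait_pair=trait_pair, observed=float(observed),
                            null=null, seed=seed)


def colocation_test(
    composite: LinkageMapSpec,
    intervals_a: list[tuple[str, float, float]],
    intervals_b: list[tuple[str, float, float]],
    trait_pair: tuple[str, str],
    n: int = 1000,
    seed: int = 0,
    within_group: bool = False,
) -> ColocationResult:
    """Observed overlap proportion plus its randomization null, end to end."""
    obs = overlap_proportion(intervals_a, intervals_b)
    null = randomize_intervals(composite, intervals_a, intervals_b,
                               n=n, seed=seed, within_group=within_group)
    return colocation_significance(obs, null, trait_pair=trait_pair, seed=seed)


def cluster_pair_tests(
    composite: LinkageMapSpec,
    clusters_a,
    clusters_b,
    trait_pair: tuple[str, str],
    n: int = 1000,
    seed: int = 0,
    drop: int = 1,
    within_group: bool = False,
) -> list[dict]:
    """Run the co-location test for every candidate cluster pair.

    A candidate pair is one cluster per trait on the same composite group
    whose cluster intervals overlap; the test statistic is the overlap
    proportion among the two clusters' member QTL intervals, against the
    genome-wide randomization null.  Returns one result row per pair.
    """
    rows = []
    for i, ca in enumerate(clusters_a):
        for j, cb in enumerate(clusters_b):
            if ca.group != cb.group:
                continue
            if ca.interval[0] > cb.interval[1] or cb.interval[0] > ca.interval[1]:
                continue
            iv_a = cluster_intervals([ca], drop=drop)
            iv_b = cluster_intervals([cb], drop=drop)
            res = colocation_test(composite, iv_a, iv_b, trait_pair,
                                  n=n, seed=seed + 97 * i + j,
                                  within_group=within_group)
            rows.append({
                "trait_pair": f"{trait_pair[0]}|{trait_pair[1]}",
                "group": ca.group,
                "cluster_a": i + 1, "cluster_b": j + 1,
                "n_intervals": len(iv_a) + len(iv_b),
                "observed": round(res.observed, 4),
                "null_mean": round(float(res.null.mean()), 4),
                "exceedance": round(res.exceedance, 4),
                "one_minus_p": round(res.one_minus_p, 4),
                "significant": res.significant,
                "n_perm": n, "seed": res.seed,
            })
    return rows


def cluster_intervals(clusters, drop: int = 1) -> list[tuple[str, float, float]]:
    """(group, lo, hi) confidence intervals of every member QTL of a trait's
    clusters at the chosen LOD drop (1 or 2)."""
    key = "ci1" if drop == 1 else "ci2"
    out = []
    for c in clusters:
        for m in c.members:
            lo, hi = m[key]
            out.append((m["group"], float(lo), float(hi)))
    return out
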