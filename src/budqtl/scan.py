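"""Single-QTL interval mapping with permutation thresholds.

The scan engine is Haley-Knott regression on a 1:1 (backcross-coded)
parental map: at each grid position the expected allele-origin genotype is
computed by conditioning on the nearest non-missing flanking markers under
inverse-Kosambi recombination probabilities, and the LOD is
(n/2) * log10(RSS0 / RSS1) from the regression of the response on that
expectation.  At a fully observed marker this equals the single-marker
regression LOD exactly.

Chromosome- and genome-wide significance thresholds come from permutation
of the response (>= 1,000 permutations for reported runs, alpha = 0.05),
using the ceil((1-alpha)(n+1))-th order statistic of the per-permutation
maximum LOD.  Support intervals are the -1 LOD and -2 LOD drops around the
peak with linear interpolation; a two-linked-QTL fit guards against ghost
peaks between two real linked QTLs.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linkage import LinkageMapSpec, inverse_kosambi

SIGNIFICANT = "significant"   # exceeds the genome-wide threshold
SUGGESTIVE = "suggestive"     # exceeds the chromosome-wide threshold only
INDICATIVE = "indicative"     # kept only if it later co-localises


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LodProfile:
    dataset: str
    group: str
    grid: np.ndarray
    lod: np.ndarray
    n: int
    peak_index: int = field(init=False)

    def __post_init__(self) -> None:
        self.peak_index = int(np.argmax(self.lod))  # leftmost tie by argmax

    @property
    def peak_position(self) -> float:
        return float(self.grid[self.peak_index])

    @property
    def peak_lod(self) -> float:
        return float(self.lod[self.peak_index])


@dataclass
class ThresholdSet:
    scope: str  # 'chromosome' | 'genome'
    group: str | None
    alpha: float
    n_perm: int
    threshold: float
    null_mean: float
    null_sd: float
    seed: int


@dataclass
class QtlRecord:
    """A detected QTL on one parental map in one dataset."""

    dataset: str
    trait: str
    population: str
    parent: str
    site: str
    year: int
    pc: int | None
    group: str
    peak_cM: float
    lod: float
    ppve_pct: float
    effect: float
    ci1: tuple[float, float]
    ci2: tuple[float, float]
    qtl_class: str
    threshold_chromosome: float = np.nan
    threshold_genome: float = np.nan

    def __post_init__(self) -> None:
        lo1, hi1 = self.ci1
        lo2, hi2 = self.ci2
        if not (lo2 <= lo1 <= self.peak_cM <= hi1 <= hi2):
            raise ValueError("support intervals must nest around the peak")


# ---------------------------------------------------------------------------
# expected genotype under the map
# ---------------------------------------------------------------------------

def expected_genotype(positions: np.ndarray, genotypes: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """E[allele origin] at each grid point given nearest non-missing flanks.

    ``positions``: ordered marker cM positions (length m).
    ``genotypes``: n x m int8/float array with 0/1 calls, -1 or NaN missing.
    Returns an n x g array of P(origin = 1 | flanking markers).
    Recombination between loci composes multiplicatively across marker
    intervals (Markov), each interval converted through the inverse Kosambi
    function; within an interval the split distances are converted directly.
    """
    positions = np.asarray(positions, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    g = np.where(np.isnan(g), -1, g).astype(np.int8)
    n, m = g.shape
    if m != len(positions):
        raise ValueError("genotype columns must match marker positions")
    grid = np.asarray(grid, dtype=float)

    valid = g >= 0
    idx = np.arange(m)
    prev = np.where(valid, idx[None, :], -1)
    prev = np.maximum.accumulate(prev, axis=1)                      # last informative <= k
    nxt = np.where(valid, idx[None, :], m)
    nxt = np.minimum.accumulate(nxt[:, ::-1], axis=1)[:, ::-1]      # first informative >= k

    # interval factors x = 1 - 2r; prefix products for multi-interval chains
    r_int = inverse_kosambi(np.diff(positions)) if m > 1 else np.array([])
    x_int = 1.0 - 2.0 * r_int
    pref = np.concatenate([[1.0], np.cumprod(x_int)])               # pref[k] = prod of intervals < k

    jl = np.clip(np.searchsorted(positions, grid, side="right") - 1, 0, m - 1)
    exact = np.isclose(grid, positions[jl])
    d_left = np.maximum(grid - positions[jl], 0.0)
    jr = np.minimum(jl + 1, m - 1)
    d_right = np.maximum(positions[jr] - grid, 0.0)
    x_pl = 1.0 - 2.0 * inverse_kosambi(d_left)                      # partial, left marker -> t
    x_pr = 1.0 - 2.0 * inverse_kosambi(d_right)                     # partial, t -> right marker

    out = np.full((n, len(grid)), 0.5)
    for j, t in enumerate(grid):
        k = int(jl[j])
        L = prev[:, k]                                              # left informative marker
        kr = k if exact[j] else min(k + 1, m - 1)
        R = nxt[:, kr]                                              # right informative marker
        hasL = L >= 0
        hasR = R < m
        sameLR = hasL & hasR & (L == R)   # single informative marker both sides
        xL = np.zeros(n)
        xR = np.zeros(n)
        sL = np.zeros(n)
        sR = np.zeros(n)
        if hasL.any():
            li = L[hasL]
            xL[hasL] = (pref[k] / pref[li]) * x_pl[j]
            sL[hasL] = np.where(g[hasL, li] == 1, 1.0, -1.0)
        if hasR.any():
            ri = R[hasR]
            base = min(k + 1, m - 1)
            xR[hasR] = (pref[ri] / pref[base]) * x_pr[j]
            sR[hasR] = np.where(g[np.nonzero(hasR)[0], ri] == 1, 1.0, -1.0)
        tL = 0.5 * (1.0 + sL * xL)          # P(gL -> 1)
        tR = 0.5 * (1.0 + sR * xR)          # P(1 -> gR)
        both = hasL & hasR & ~sameLR
        onlyL = (hasL & ~hasR) | sameLR
        onlyR = hasR & ~hasL
        denom = 0.5 * (1.0 + sL * xL * sR * xR)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[both, j] = (tL[both] * tR[both]) / denom[both]
        out[onlyL, j] = tL[onlyL]
        out[onlyR, j] = tR[onlyR]
        if exact[j]:  # observed call at the marker itself is definitive
            obs = valid[:, k]
            out[obs, j] = g[obs, k]
    return np.clip(out, 0.0, 1.0)


def make_grid(positions: np.ndarray, step: float = 1.0) -> np.ndarray:
    """Scan grid over [0, group span] at fixed step, plus the marker positions."""
    positions = np.asarray(positions, dtype=float)
    lo, hi = float(positions.min()), float(positions.max())
    grid = np.arange(lo, hi + step / 2, step)
    grid = np.union1d(np.round(grid, 6), np.round(positions, 6))
    return grid


# ---------------------------------------------------------------------------
# the scan itself
# ---------------------------------------------------------------------------

def _lod_from_expectation(E: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(lod, ppve, effect) per grid column for response y (no missing)."""
    n = len(y)
    yc = y - y.mean()
    syy = float(yc @ yc)
    Xc = E - E.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    sxy = yc @ Xc
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where((sxx > 0) & (syy > 0), sxy**2 / (sxx * syy), 0.0)
    r2 = np.clip(r2, 0.0, 1.0 - 1e-12)
    lod = -(n / 2.0) * np.log10(1.0 - r2)
    effect = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    return lod, 100.0 * r2, effect


def interval_scan(
    map_positions: pd.Series,
    genotypes: pd.DataFrame,
    response: pd.Series,
    step: float = 1.0,
    dataset: str = "",
    group: str = "",
) -> tuple[LodProfile, dict]:
    """Haley-Knott scan of one linkage group.

    ``map_positions``: marker -> cM for the group (one parent's map).
    ``genotypes``: progeny x marker 0/1/NaN calls for those markers.
    ``response``: numeric phenotype per progeny (clone mean or PC score).
    Returns the LOD profile plus peak statistics (effect, PPVE).
    """
    markers = list(map_positions.sort_values().index)
    if len(markers) < 2:
        _warnings.warn(f"group {group}: fewer than 2 markers; single-marker scan")
    shared = genotypes.index.intersection(response.dropna().index)
    if len(shared) < 20:
        raise ValueError(f"dataset {dataset}: only {len(shared)} progeny with data")
    if len(shared) < 50:
        _warnings.warn(f"dataset {dataset}: fewer than 50 progeny with data")
    g = genotypes.loc[shared, markers].to_numpy(dtype=float)
    y = response.loc[shared].to_numpy(dtype=float)
    pos = map_positions[markers].to_numpy(dtype=float)
    grid = make_grid(pos, step)
    E = expected_genotype(pos, g, grid)
    lod, ppve, effect = _lod_from_expectation(E, y)
    profile = LodProfile(dataset=dataset, group=group, grid=grid, lod=lod, n=len(y))
    i = profile.peak_index
    return profile, {"ppve_pct": float(ppve[i]), "effect": float(effect[i])}


def genome_scan(
    map_spec: LinkageMapSpec,
    genotypes: pd.DataFrame,
    response: pd.Series,
    step: float = 1.0,
    dataset: str = "",
) -> dict[str, tuple[LodProfile, dict]]:
    """Scan every linkage group that has genotyped markers."""
    out = {}
    for grp in map_spec.groups:
        posn = map_spec.group_positions(grp)
        posn = posn[[m for m in posn.index if m in genotypes.columns]]
        if len(posn) < 1:
            continue
        out[grp] = interval_scan(posn, genotypes, response, step=step,
                                 dataset=dataset, group=grp)
    return out


# ---------------------------------------------------------------------------
# permutation thresholds
# ---------------------------------------------------------------------------

def order_statistic_threshold(maxima: np.ndarray, alpha: float) -> float:
    """ceil((1-alpha)(n+1))-th order statistic of permuted maxima."""
    n = len(maxima)
    k = min(math.ceil((1.0 - alpha) * (n + 1)), n)
    return float(np.sort(maxima)[k - 1])


def permutation_thresholds(
    map_spec: LinkageMapSpec,
    genotypes: pd.DataFrame,
    response: pd.Series,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    step: float = 1.0,
    reporting: bool = True,
) -> tuple[dict[str, ThresholdSet], ThresholdSet]:
    """Chromosome-wise and genome-wide permutation thresholds, one shuffle set.

    The response is permuted against the genotypes; each permutation's
    maximum LOD per group (chromosome scope) and over all groups (genome
    scope) feeds the order-statistic rule.  Fewer than 100 permutations are
    refused for reporting runs.
    """
    if reporting and n_perm < 1000:
        raise ValueError("reported thresholds require >= 1,000 permutations")
    if n_perm < 100 and reporting:
        raise ValueError("refusing < 100 permutations outside test mode")
    shared = genotypes.index.intersection(response.dropna().index)
    y = response.loc[shared].to_numpy(dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
    perms -= perms.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(perms, axis=1, keepdims=True)
    perms /= np.where(norms > 0, norms, 1.0)

    group_slices: dict[str, slice] = {}
    blocks = []
    start = 0
    for grp in map_spec.groups:
        posn = map_spec.group_positions(grp)
        posn = posn[[m for m in posn.index if m in genotypes.columns]]
        if len(posn) < 1:
            continue
        g = genotypes.loc[shared, posn.index].to_numpy(dtype=float)
        grid = make_grid(posn.to_numpy(dtype=float), step)
        E = expected_genotype(posn.to_numpy(dtype=float), g, grid)
        Xc = E - E.mean(axis=0)
        colnorm = np.linalg.norm(Xc, axis=0)
        Xn = Xc / np.where(colnorm > 0, colnorm, 1.0)
        Xn[:, colnorm == 0] = 0.0
        blocks.append(Xn)
        group_slices[grp] = slice(start, start + Xn.shape[1])
        start += Xn.shape[1]
    X = np.concatenate(blocks, axis=1)
    corr = perms @ X
    r2 = np.clip(corr**2, 0.0, 1.0 - 1e-12)
    lod = -(n / 2.0) * np.log10(1.0 - r2)

    chrom: dict[str, ThresholdSet] = {}
    for grp, sl in group_slices.items():
        mx = lod[:, sl].max(axis=1)
        chrom[grp] = ThresholdSet(
            "chromosome", grp, alpha, n_perm, order_statistic_threshold(mx, alpha),
            float(mx.mean()), float(mx.std(ddof=1)), seed)
    gmax = lod.max(axis=1)
    genome = ThresholdSet(
        "genome", None, alpha, n_perm, order_statistic_threshold(gmax, alpha),
        float(gmax.mean()), float(gmax.std(ddof=1)), seed)
    return chrom, genome


# ---------------------------------------------------------------------------
# support intervals and classification
# ---------------------------------------------------------------------------

def support_interval(profile: LodProfile, drop: float) -> tuple[float, float]:
    """Contiguous region around the peak with LOD >= peak - drop.

    Crossings are linearly interpolated between grid points; the interval is
    truncated at the group ends.  A flat profile spans the whole group.
    """
    grid, lod = profile.grid, profile.lod
    peak = profile.peak_index
    target = profile.peak_lod - drop
    if np.ptp(lod) == 0.0:
        _warnings.warn("flat LOD profile; support interval spans the group")
        return float(grid[0]), float(grid[-1])
    lo = float(grid[0])
    for i in range(peak, 0, -1):
        if lod[i - 1] < target:
            frac = (lod[i] - target) / (lod[i] - lod[i - 1])
            lo = float(grid[i] - frac * (grid[i] - grid[i - 1]))
            break
    hi = float(grid[-1])
    for i in range(peak, len(grid) - 1):
        if lod[i + 1] < target:
            frac = (lod[i] - target) / (lod[i] - lod[i + 1])
            hi = float(grid[i] + frac * (grid[i + 1] - grid[i]))
            break
    return lo, hi


def classify_qtl(
    profile: LodProfile,
    peak_stats: dict,
    chrom_threshold: float,
    genome_threshold: float,
    context: dict | None = None,
) -> QtlRecord:
    """Attach class and -1/-2 LOD support intervals to a scan peak.

    significant >= genome-wide threshold, suggestive >= chromosome-wide,
    anything else is candidate-indicative (kept only if it later
    co-localises with significant QTLs).
    """
    context = context or {}
    peak = profile.peak_lod
    if peak >= genome_threshold:
        cls = SIGNIFICANT
    elif peak >= chrom_threshold:
        cls = SUGGESTIVE
    else:
        cls = INDICATIVE
    ci1 = support_interval(profile, 1.0)
    ci2 = support_interval(profile, 2.0)
    return QtlRecord(
        dataset=profile.dataset,
        trait=context.get("trait", ""),
        population=context.get("population", ""),
        parent=context.get("parent", ""),
        site=context.get("site", ""),
        year=int(context.get("year", 0)),
        pc=context.get("pc"),
        group=profile.group,
        peak_cM=round(profile.peak_position, 1),
        lod=round(peak, 3),
        ppve_pct=round(peak_stats["ppve_pct"], 2),
        effect=round(peak_stats["effect"], 4),
        ci1=(round(ci1[0], 1), round(ci1[1], 1)),
        ci2=(round(ci2[0], 1), round(ci2[1], 1)),
        qtl_class=cls,
        threshold_chromosome=round(chrom_threshold, 3),
        threshold_genome=round(genome_threshold, 3),
    )


def phenotype_for_scan(
    heights: pd.DataFrame | None = None,
    composite: "CompositePhenotype | None" = None,
    site: str | None = None,
    year: int | None = None,
) -> pd.Series:
    """Per-progeny response vector for one dataset.

    Height: clone mean over the ramets in scope (site x year).  Phenology:
    the per-tree factorial score of one retained component.
    """
    if composite is not None:
        resp = composite.scores.dropna()
    else:
        sub = heights[(heights["site"] == site) & (heights["year"] == int(year))]
        resp = sub.groupby("tree_id")["height_mm"].mean().dropna()
    if len(resp) < 20:
        raise ValueError(f"only {len(resp)} progeny with phenotype data")
    if len(resp) < 50:
        _warnings.warn("fewer than 50 progeny with phenotype data")
    return resp


def retain_indicative(
    candidates: list, significant: list, min_colocated: int = 2
) -> list:
    """Keep candidate-indicative QTLs whose projected -1 LOD interval
    overlaps at least ``min_colocated`` significant QTLs (any dataset).

    Operates on projected records (dicts or QtlRecords with .group/.ci1 on
    the composite map).
    """
    kept = []
    for cand in candidates:
        cg, (clo, chi) = cand["group"], cand["ci1"]
        hits = sum(
            1 for s in significant
            if s["group"] == cg and s["ci1"][0] <= chi and clo <= s["ci1"][1]
        )
        if hits >= min_colocated:
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# two-linked-QTL (ghost) check
# ---------------------------------------------------------------------------

def two_qtl_test(
    map_positions: pd.Series,
    genotypes: pd.DataFrame,
    response: pd.Series,
    single_threshold: float,
    step: float = 5.0,
    min_separation: float = 15.0,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Compare a two-position model (H2) against the best single QTL (H1).

    H2 is a two-column Haley-Knott fit over a coarse position grid; its gain
    over H1 is judged by permuting the H1 residuals.  Returns the decision
    (0, 1 or 2 QTLs), best positions and the permutation p-value.  H0 vs H1
    uses the supplied single-QTL threshold.
    """
    markers = list(map_positions.sort_values().index)
    shared = genotypes.index.intersection(response.dropna().index)
    g = genotypes.loc[shared, markers].to_numpy(dtype=float)
    y = response.loc[shared].to_numpy(dtype=float)
    pos = map_positions[markers].to_numpy(dtype=float)
    span = pos.max() - pos.min()
    if span < 40.0 or len(markers) < 3:
        return {"decision": None, "reason": "group too short or too sparse for the two-QTL fit"}
    grid = np.arange(pos.min(), pos.max() + step / 2, step)
    E = expected_genotype(pos, g, grid)
    n = len(y)
    rng = np.random.default_rng(seed)

    lod1, _, _ = _lod_from_expectation(E, y)
    best1 = int(np.argmax(lod1))
    if lod1[best1] < single_threshold:
        return {"decision": 0, "lod1": float(lod1[best1]), "pos1": float(grid[best1])}

    pairs = [(i, j) for i in range(len(grid)) for j in range(i + 1, len(grid))
             if grid[j] - grid[i] >= min_separation]
    if not pairs:
        return {"decision": 1, "lod1": float(lod1[best1]), "pos1": float(grid[best1])}

    def _fit_stats(yv: np.ndarray) -> tuple[float, float, int]:
        """(best RSS1, best RSS2, best pair index) for a response vector."""
        yc = yv - yv.mean()
        syy = float(yc @ yc)
        l1, _, _ = _lod_from_expectation(E, yv)
        rss1 = syy * 10.0 ** (-2.0 * l1.max() / n)
        rss2 = rss1
        bp = -1
        Ec = E - E.mean(axis=0)
        cross = yc @ Ec
        for pi, (i, j) in enumerate(pairs):
            a, b = Ec[:, i], Ec[:, j]
            saa, sbb, sab = a @ a, b @ b, a @ b
            det = saa * sbb - sab * sab
            if det <= 1e-10:
                continue
            ca, cb = cross[i], cross[j]
            expl = (sbb * ca * ca - 2 * sab * ca * cb + saa * cb * cb) / det
            rss = syy - expl
            if rss < rss2:
                rss2, bp = rss, pi
        return rss1, rss2, bp

    rss1, rss2, bp = _fit_stats(y)
    t_obs = (n / 2.0) * math.log10(max(rss1, 1e-300) / max(rss2, 1e-300))

    # permute residuals of the best single-QTL fit
    yc = y - y.mean()
    a = E[:, best1] - E[:, best1].mean()
    beta = (yc @ a) / (a @ a) if a @ a > 0 else 0.0
    fitted = y.mean() + beta * a
    resid = y - fitted
    t_null = np.empty(n_perm)
    for p in range(n_perm):
        ystar = fitted + rng.permutation(resid)
        r1, r2, _ = _fit_stats(ystar)
        t_null[p] = (n / 2.0) * math.log10(max(r1, 1e-300) / max(r2, 1e-300))
    pval = float((np.sum(t_null >= t_obs) + 1) / (n_perm + 1))
    decision = 2 if pval < alpha else 1
    out = {
        "decision": decision,
        "lod1": float(lod1[best1]),
        "pos1": float(grid[best1]),
        "statistic": float(t_obs),
        "p": pval,
        "n_perm": n_perm,
    }
    if bp >= 0:
        i, j = pairs[bp]
        out["pos2"] = (float(grid[i]), float(grid[j]))
    return out
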