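"""Synthetic two-way pseudo-testcross families with clonal phenotyping.

Emulates the study system the package analyses: two unrelated full-sib
conifer families whose progeny are clonally replicated (six ramets each,
three indoor and three outdoor blocks), scored for bud flush (stages 0-6)
and bud set (stages 0-5) on a fixed observation calendar over multiple
years, and measured for annual height growth.  Meiosis is simulated as a
Markov chain over adjacent marker intervals with per-interval recombination
probability equal to the inverse Kosambi transform of the interval length,
which matches the map function used downstream without an explicit
interference model.

Phenology follows a latent-timing threshold model: each ramet-year has a
latent timing (genetic value + clone deviation + block + year + environment
+ residual, in days) and reaches stage s once the date passes
timing + offset(s) + a per-stage jitter, so recorded stage sequences are
ordinal, calendar-censored and non-decreasing, as in the field data.
Planted QTLs are carried as hidden loci on the same simulated gametes and
written to a truth file together with the true map.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .linkage import ANCHOR, MATERNAL, PATERNAL, LinkageMapSpec, inverse_kosambi, roman

SITES = ("VES", "AAFC")  # outdoor blocks / indoor (controlled photoperiod) blocks

FLUSH = "bud_flush"
SET = "bud_set"
HEIGHT = "height"

N_STAGES = {FLUSH: 6, SET: 5}  # stages 0..6 and 0..5


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class TrueMapConfig:
    """True-map layout: 12 groups totalling ~2,100 cM by default."""

    n_groups: int = 12
    group_lengths: Sequence[float] = (175.0,) * 12
    markers_per_group: Sequence[int] | int = 40
    class_mix: tuple[float, float, float] = (0.35, 0.35, 0.30)  # maternal, paternal, anchor
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.markers_per_group, int):
            self.markers_per_group = (self.markers_per_group,) * self.n_groups
        if len(self.group_lengths) != self.n_groups or len(self.markers_per_group) != self.n_groups:
            raise ValueError("group_lengths / markers_per_group must match n_groups")
        if any(l <= 0 for l in self.group_lengths):
            raise ValueError("group lengths must be positive")
        if any(m < 1 for m in self.markers_per_group):
            raise ValueError("marker counts must be positive")
        if abs(sum(self.class_mix) - 1.0) > 1e-8:
            raise ValueError("class mix fractions must sum to 1")


@dataclass
class PlantedQtl:
    """A planted additive QTL: effect in units of single-ramet phenotype SD.

    ``active`` is None (all contexts) or a set of (year, site) pairs in
    which the QTL contributes to the genetic value.
    """

    trait: str
    group: str
    position_cM: float
    parent: str  # 'maternal' | 'paternal'
    effect_sd: float
    active: frozenset[tuple[int, str]] | None = None

    def __post_init__(self) -> None:
        if self.trait not in (FLUSH, SET, HEIGHT):
            raise ValueError(f"unknown trait {self.trait!r}")
        if not np.isfinite(self.effect_sd):
            raise ValueError("QTL effect must be finite")
        if self.active is not None:
            self.active = frozenset((int(y), s) for y, s in self.active)

    def is_active(self, year: int, site: str) -> bool:
        return self.active is None or (year, site) in self.active

    @property
    def qtl_id(self) -> str:
        return f"q_{self.trait}_{self.group}_{self.position_cM:g}"


@dataclass
class TrialDesign:
    """Clonal trial layout and phenotype-model parameters.

    Variances are on the latent scale: days for phenology timings, mm for
    height.  ``repeatability`` sets the clone-level share of latent variance
    (between-clone / total), before small block effects.
    """

    n_progeny: int = 260
    ramets_per_progeny: int = 6
    blocks_indoor: int = 3
    blocks_outdoor: int = 3
    years: tuple[int, ...] = (2004, 2005)
    flush_calendar: tuple[int, ...] = tuple(range(118, 181, 2))
    set_calendar: tuple[int, ...] = tuple(range(182, 287, 7))
    flush_base_day: float = 140.0
    set_base_day: float = 225.0
    flush_stage_offsets: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0)
    set_stage_offsets: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0)
    timing_sd_days: float = 6.0
    stage_jitter_sd_days: float = 12.0
    block_sd_days: float = 1.0
    year_sd_days: float = 2.0
    site_shift_days: float = 2.0
    height_base_mm: float = 300.0
    height_sd_mm: float = 50.0
    height_block_sd_mm: float = 5.0
    height_year_sd_mm: float = 10.0
    repeatability: dict = field(
        default_factory=lambda: {FLUSH: 0.45, SET: 0.43, HEIGHT: 0.60}
    )

    def __post_init__(self) -> None:
        if self.n_progeny < 2:
            raise ValueError("need at least two progeny")
        for r in self.repeatability.values():
            if not 0.0 <= r < 1.0:
                raise ValueError("repeatability target must lie in [0, 1)")
        if len(self.flush_stage_offsets) != N_STAGES[FLUSH]:
            raise ValueError("bud flush needs offsets for stages 1..6")
        if len(self.set_stage_offsets) != N_STAGES[SET]:
            raise ValueError("bud set needs offsets for stages 1..5")

    @property
    def blocks(self) -> list[tuple[str, str]]:
        out = [(f"out{b+1}", "VES") for b in range(self.blocks_outdoor)]
        ind = [(f"in{b+1}", "AAFC") for b in range(self.blocks_indoor)]
        return out + ind

    def calendar(self, trait: str) -> tuple[int, ...]:
        return self.flush_calendar if trait == FLUSH else self.set_calendar

    def stage_offsets(self, trait: str) -> tuple[float, ...]:
        return self.flush_stage_offsets if trait == FLUSH else self.set_stage_offsets

    def base(self, trait: str) -> float:
        return self.flush_base_day if trait == FLUSH else self.set_base_day

    def latent_sd(self, trait: str) -> float:
        return self.height_sd_mm if trait == HEIGHT else self.timing_sd_days

    def scan_variance(self, trait: str, n_ramets: int | None = None) -> float:
        """Variance of clone means over ``n_ramets`` ramets, in squared SD units."""
        r = self.repeatability[trait]
        k = n_ramets if n_ramets is not None else self.blocks_outdoor
        return r + (1.0 - r) / k


def effect_for_ppve(ppve_percent: float, design: TrialDesign, trait: str,
                    n_ramets: int | None = None) -> float:
    """Additive effect (phenotype-SD units) giving the target PPVE on clone means.

    PPVE is the share of clone-mean variance explained by the locus in a
    1:1 backcross coding, i.e. (a/2)^2 / Var(clone mean); solved for a.
    """
    v = ppve_percent / 100.0
    if not 0.0 < v <= 0.25:
        raise ValueError("target PPVE must lie in (0, 25] percent")
    return float(2.0 * np.sqrt(v * design.scan_variance(trait, n_ramets)))


# ---------------------------------------------------------------------------
# parents and map
# ---------------------------------------------------------------------------

def simulate_parents_and_map(config: TrueMapConfig) -> pd.DataFrame:
    """Draw the true map: marker positions, segregation classes and phases.

    Returns a frame with columns group, marker, position_cM, seg_class,
    phase.  Marker ids encode the class (a/f/m prefix) so that deterministic
    tie-breaks and anchor-based orientation are reproducible.  Each group is
    guaranteed at least two anchors (needed later for merging).
    """
    rng = np.random.default_rng(config.seed)
    prefix = {MATERNAL: "f", PATERNAL: "m", ANCHOR: "a"}
    rows = []
    for gi in range(config.n_groups):
        length = float(config.group_lengths[gi])
        m = int(config.markers_per_group[gi])
        grid = np.arange(0.0, length + 1e-9, 0.5)
        pos = np.sort(rng.choice(grid, size=min(m, len(grid)), replace=False))
        classes = _assign_classes(m, config.class_mix, rng)
        for k, (p, cls) in enumerate(zip(pos, classes)):
            rows.append({
                "group": roman(gi + 1),
                "marker": f"{prefix[cls]}{gi + 1:02d}_{k:03d}",
                "position_cM": float(p),
                "seg_class": cls,
                "phase": int(rng.integers(0, 2)),
            })
    return pd.DataFrame(rows)


def _assign_classes(m: int, mix: tuple[float, float, float], rng: np.random.Generator) -> list[str]:
    classes = [MATERNAL, PATERNAL, ANCHOR]
    counts = np.floor(np.asarray(mix) * m).astype(int)
    while counts.sum() < m:
        counts[int(np.argmax(np.asarray(mix) * m - counts))] += 1
    # merging needs >= 2 anchors per group
    while counts[2] < min(2, m) and counts[:2].sum() > 0:
        counts[int(np.argmax(counts[:2]))] -= 1
        counts[2] += 1
    labels = sum(([c] * n for c, n in zip(classes, counts)), [])
    rng.shuffle(labels)
    return labels


def true_map_spec(true_map: pd.DataFrame, parent: str | None = None) -> LinkageMapSpec:
    """View the truth table as a LinkageMapSpec (optionally one parent's frame)."""
    df = true_map
    if parent is not None:
        df = df[df["seg_class"].isin([parent, ANCHOR])]
    return LinkageMapSpec(
        f"true_{parent or 'full'}", "parental" if parent else "composite",
        df[["group", "marker", "position_cM"]].copy(),
    )


# ---------------------------------------------------------------------------
# progeny genotypes
# ---------------------------------------------------------------------------

@dataclass
class ProgenyGenotypes:
    """Coded allele-origin tables per informative parent, plus hidden QTL loci."""

    maternal: pd.DataFrame
    paternal: pd.DataFrame
    qtl: pd.DataFrame  # progeny x planted-QTL id, never released to mapping

    @property
    def progeny(self) -> pd.Index:
        return self.maternal.index


def _gametes(positions: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n haplotypes over ordered loci; Markov switches at inverse-Kosambi rates."""
    m = len(positions)
    h = np.empty((n, m), dtype=bool)
    h[:, 0] = rng.integers(0, 2, size=n).astype(bool)
    if m > 1:
        r = inverse_kosambi(np.diff(positions))
        h[:, 1:] = rng.random((n, m - 1)) < r
        h = np.logical_xor.accumulate(h, axis=1)
    return h.astype(np.int8)


def simulate_progeny(
    true_map: pd.DataFrame,
    n_progeny: int,
    seed: int,
    qtls: Sequence[PlantedQtl] = (),
    missing_rate: float = 0.005,
    distorted_markers: dict[str, float] | None = None,
    progeny_prefix: str = "t",
) -> ProgenyGenotypes:
    """Simulate progeny allele-origin genotypes for both parents.

    Planted QTLs are inserted as hidden loci on the transmitting parent's
    gametes so that marker-QTL linkage follows the same recombination
    process as the released markers.  ``distorted_markers`` maps marker id
    to a transmission bias (probability of allele 1), used to exercise the
    distortion filter; biased markers are redrawn independently.
    """
    if n_progeny < 2:
        raise ValueError("n_progeny must be >= 2")
    known = set(true_map["marker"])
    for q in qtls:
        if q.group not in set(true_map["group"]):
            raise ValueError(f"planted QTL references unknown group {q.group}")
    rng = np.random.default_rng(seed)
    progeny = pd.Index([f"{progeny_prefix}{i + 1:04d}" for i in range(n_progeny)], name="tree_id")
    distorted_markers = distorted_markers or {}

    out: dict[str, pd.DataFrame] = {}
    qtl_cols: dict[str, np.ndarray] = {}
    for parent in (MATERNAL, PATERNAL):
        cols: list[str] = []
        mats: list[np.ndarray] = []
        for gi, grp in enumerate(dict.fromkeys(true_map["group"])):
            sub = true_map[(true_map["group"] == grp)
                           & (true_map["seg_class"].isin([parent, ANCHOR]))]
            loci = [(float(p), m) for p, m in zip(sub["position_cM"], sub["marker"])]
            for q in qtls:
                if q.parent == parent and q.group == grp:
                    loci.append((float(q.position_cM), q.qtl_id))
            loci.sort()
            if not loci:
                continue
            pos = np.array([p for p, _ in loci])
            h = _gametes(pos, n_progeny, rng)
            for j, (_, mk) in enumerate(loci):
                if mk in known:
                    cols.append(mk)
                    mats.append(h[:, j].copy())
                else:
                    qtl_cols[mk] = h[:, j].copy()
        if not mats:
            out[parent] = pd.DataFrame(index=progeny)
            continue
        g = np.stack(mats, axis=1).astype(float)
        for mk, bias in distorted_markers.items():
            if mk in cols:
                j = cols.index(mk)
                g[:, j] = (rng.random(n_progeny) < bias).astype(float)
        if missing_rate > 0:
            g[rng.random(g.shape) < missing_rate] = np.nan
        out[parent] = pd.DataFrame(g, index=progeny, columns=cols)
    qtl_df = pd.DataFrame(
        {q.qtl_id: qtl_cols[q.qtl_id].astype(float) for q in qtls}, index=progeny
    )
    return ProgenyGenotypes(out[MATERNAL], out[PATERNAL], qtl_df)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _genetic_values(
    genotypes: ProgenyGenotypes,
    qtls: Sequence[PlantedQtl],
    design: TrialDesign,
    trait: str,
    rng: np.random.Generator,
) -> dict[tuple[int, str], np.ndarray]:
    """Per-(year, site) clone genetic values in latent units (SD * latent_sd).

    The polygenic clone deviation tops up the QTL variance to the
    repeatability target; it is constant across contexts.
    """
    n = len(genotypes.progeny)
    sd = design.latent_sd(trait)
    r = design.repeatability[trait]
    active_qtls = [q for q in qtls if q.trait == trait]
    worst = 0.0
    for year in design.years:
        for site in SITES:
            worst = max(worst, sum((q.effect_sd ** 2) / 4.0
                                   for q in active_qtls if q.is_active(year, site)))
    poly_var = max(r - worst, 0.0)
    poly = rng.normal(0.0, np.sqrt(poly_var) * sd, size=n)
    values = {}
    for year in design.years:
        for site in SITES:
            g = poly.copy()
            for q in active_qtls:
                if not q.is_active(year, site):
                    continue
                x = genotypes.qtl[q.qtl_id].to_numpy()
                g = g + q.effect_sd * sd * (x - 0.5)
            values[(int(year), site)] = g
    return values


def simulate_phenotypes(
    genotypes: ProgenyGenotypes,
    qtls: Sequence[PlantedQtl],
    design: TrialDesign,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate the phenology observation table, height table and truth record.

    Phenology rows: tree_id, ramet, block, site, year, date (ISO), trait,
    stage.  Heights: tree_id, ramet, block, site, year, height_mm.
    """
    for q in qtls:
        if q.qtl_id not in genotypes.qtl.columns:
            raise ValueError(f"planted QTL {q.qtl_id} has no simulated genotypes")
    rng = np.random.default_rng(seed)
    n = len(genotypes.progeny)
    trees = genotypes.progeny.to_numpy()
    blocks = design.blocks

    phen_frames = []
    height_frames = []
    truth_ppve: list[dict] = []

    for trait in (FLUSH, SET, HEIGHT):
        r = design.repeatability[trait]
        sd = design.latent_sd(trait)
        resid_sd = np.sqrt(1.0 - r) * sd
        gvals = _genetic_values(genotypes, qtls, design, trait, rng)
        if trait == HEIGHT:
            block_eff = {b: rng.normal(0.0, design.height_block_sd_mm) for b, _ in blocks}
            year_eff = {y: rng.normal(0.0, design.height_year_sd_mm) for y in design.years}
        else:
            block_eff = {b: rng.normal(0.0, design.block_sd_days) for b, _ in blocks}
            year_eff = {y: rng.normal(0.0, design.year_sd_days) for y in design.years}
        site_eff = {"VES": 0.0, "AAFC": design.site_shift_days if trait != HEIGHT else 0.0}

        for year in design.years:
            for ramet, (block, site) in enumerate(blocks, start=1):
                latent = (
                    gvals[(int(year), site)]
                    + block_eff[block]
                    + year_eff[year]
                    + site_eff[site]
                    + rng.normal(0.0, resid_sd, size=n)
                )
                if trait == HEIGHT:
                    height_frames.append(pd.DataFrame({
                        "tree_id": trees,
                        "ramet": ramet,
                        "block": block,
                        "site": site,
                        "year": int(year),
                        "height_mm": np.round(design.height_base_mm + latent, 1),
                    }))
                    continue
                timing = design.base(trait) + latent
                offs = np.asarray(design.stage_offsets(trait))
                reach = timing[:, None] + offs[None, :] + rng.normal(
                    0.0, design.stage_jitter_sd_days, size=(n, len(offs))
                )
                reach = np.maximum.accumulate(reach, axis=1)  # monotone thresholds
                cal = np.asarray(design.calendar(trait))
                stage = (cal[None, None, :] >= reach[:, :, None]).sum(axis=1)
                dates = [f"{int(year)}-{d:03d}" for d in cal]
                phen_frames.append(pd.DataFrame({
                    "tree_id": np.repeat(trees, len(cal)),
                    "ramet": ramet,
                    "block": block,
                    "site": site,
                    "year": int(year),
                    "date": np.tile(dates, n),
                    "julian_day": np.tile(cal, n),
                    "trait": trait,
                    "stage": stage.reshape(-1),
                }))

    phenology = pd.concat(phen_frames, ignore_index=True)
    heights = pd.concat(height_frames, ignore_index=True)
    phenology["date"] = [_iso(d) for d in phenology.pop("date")]

    for q in qtls:
        v = design.scan_variance(q.trait)
        truth_ppve.append({
            **dataclasses.asdict(q),
            "active": None if q.active is None else sorted([list(a) for a in q.active]),
            "ppve_clone_mean_pct": round(100.0 * (q.effect_sd ** 2 / 4.0) / v, 2),
        })
    truth = {
        "design": {k: v for k, v in dataclasses.asdict(design).items()},
        "qtls": truth_ppve,
        "seed": int(seed),
    }
    return phenology, heights, truth


def _iso(tag: str) -> str:
    """'YYYY-JJJ' (year + Julian day) -> ISO date."""
    year, jday = tag.split("-")
    ts = pd.Timestamp(int(year), 1, 1) + pd.Timedelta(days=int(jday) - 1)
    return ts.strftime("%Y-%m-%d")


def julian_day(dates: Iterable[str]) -> np.ndarray:
    """ISO dates -> Julian day of year."""
    return pd.to_datetime(list(dates)).dayofyear.to_numpy()


# ---------------------------------------------------------------------------
# whole-cross convenience
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCross:
    name: str
    true_map: pd.DataFrame
    genotypes: ProgenyGenotypes
    phenology: pd.DataFrame
    heights: pd.DataFrame
    qtls: list[PlantedQtl]
    truth: dict


def default_planted_qtls(
    true_map: pd.DataFrame, design: TrialDesign, rng_or_seed: int | np.random.Generator = 0
) -> list[PlantedQtl]:
    """A realistic QTL architecture for the default study conditions.

    Effects are chosen to span the reported PPVE ranges (3.0-16.4% bud
    flush, 2.7-22.2% bud set, 2.5-10.5% height growth); some loci are made
    context-specific (single year or indoor-only) to exercise the stability
    tabulations.
    """
    rng = rng_or_seed if isinstance(rng_or_seed, np.random.Generator) else np.random.default_rng(rng_or_seed)
    groups = list(dict.fromkeys(true_map["group"]))
    years = design.years
    plan = {
        FLUSH: [3.0, 6.0, 10.0, 16.4],
        SET: [2.7, 5.0, 8.0, 14.0, 22.2],
        HEIGHT: [2.5, 5.0, 7.5, 10.5],
    }
    qtls: list[PlantedQtl] = []
    gi = 0
    for trait, ppves in plan.items():
        for j, ppve in enumerate(ppves):
            grp = groups[gi % len(groups)]
            gi += 1
            sub = true_map[true_map["group"] == grp]
            pos = float(sub["position_cM"].iloc[int(rng.integers(0, len(sub)))])
            parent = MATERNAL if (gi % 2 == 0) else PATERNAL
            if j == len(ppves) - 2 and len(years) > 1:
                active = frozenset((years[-1], s) for s in SITES)  # second-year specific
            elif j == len(ppves) - 1 and trait != HEIGHT:
                active = frozenset((y, "AAFC") for y in years)  # indoor (photoperiod) specific
            else:
                active = None
            qtls.append(PlantedQtl(trait, grp, pos, parent,
                                   effect_for_ppve(ppve, design, trait), active))
    return qtls


def simulate_cross(
    name: str,
    map_config: TrueMapConfig | None,
    design: TrialDesign,
    seed: int,
    qtls: Sequence[PlantedQtl] | None = None,
    missing_rate: float = 0.005,
    distorted_markers: dict[str, float] | None = None,
    true_map: pd.DataFrame | None = None,
) -> SimulatedCross:
    """Simulate one full-sib family end to end (map, genotypes, phenotypes).

    Pass ``true_map`` to reuse a genome layout across crosses (two unrelated
    families segregate for subsets of the same species map).
    """
    if true_map is None:
        true_map = simulate_parents_and_map(map_config)
    if qtls is None:
        qtls = default_planted_qtls(true_map, design, np.random.default_rng(seed + 1))
    genotypes = simulate_progeny(
        true_map, design.n_progeny, seed + 2, qtls=qtls,
        missing_rate=missing_rate, distorted_markers=distorted_markers,
        progeny_prefix=f"{name}_",
    )
    phenology, heights, truth = simulate_phenotypes(genotypes, qtls, design, seed + 3)
    truth["map"] = true_map.to_dict(orient="records")
    truth["name"] = name
    return SimulatedCross(name, true_map, genotypes, phenology, heights, list(qtls), truth)
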