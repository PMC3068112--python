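"""Panel filtering, map summaries and the consolidated results report.

Covers the bookkeeping around the mapping itself: the SNP-panel quality
filter (minimum bead-array quality score of 0.25 plus a segregation
requirement, with one SNP kept per gene by least missing data), per-map
summary statistics (positioned markers, length, average density), and the
consolidated report of QTL counts, PPVE ranges and stability percentages.
Percentages are rounded half-up to match how such tables are printed.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .linkage import LinkageMapSpec


def round_half_up(x: float, digits: int = 0) -> float | int:
    """Decimal half-up rounding (1100/1536 -> 72%, not banker's 71%)."""
    q = decimal.Decimal(10) ** -digits
    v = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(v) if digits > 0 else int(v)


def percent(numerator: float, denominator: float, digits: int = 0) -> float | int:
    """Printed-style percentage with half-up rounding."""
    if denominator == 0:
        return 0 if digits == 0 else 0.0
    return round_half_up(100.0 * numerator / denominator, digits)


# ---------------------------------------------------------------------------
# SNP panel filter
# ---------------------------------------------------------------------------

def filter_snp_panel(panel: pd.DataFrame, min_score: float = 0.25) -> dict:
    """Bead-array quality filter and per-gene SNP selection.

    ``panel`` columns: snp_id, gene_id, source, score (in [0, 1]),
    segregating (bool), missing_frac.  A SNP is retained when its quality
    score is at least ``min_score`` AND it segregates in the cross.  When a
    gene keeps several SNPs, the one with least missing data is selected
    for mapping.  Returns counts in the shape of a genotyping-success
    table, with per-source percentages.
    """
    if panel.empty:
        raise ValueError("empty SNP panel")
    if panel["snp_id"].duplicated().any():
        dup = panel.loc[panel["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicated SNP id: {dup}")
    score_ok = panel["score"] >= min_score
    retained = panel[score_ok & panel["segregating"]].copy()
    per_source = {}
    for src, sub in panel.groupby("source"):
        s_ok = sub["score"] >= min_score
        seg = sub[s_ok & sub["segregating"]]
        per_source[src] = {
            "assayed": int(len(sub)),
            "score_pass": int(s_ok.sum()),
            "score_pass_pct": percent(s_ok.sum(), len(sub)),
            "retained": int(len(seg)),
            "retained_pct": percent(len(seg), len(sub)),
        }
    selected = (
        retained.sort_values(["gene_id", "missing_frac", "snp_id"])
        .groupby("gene_id", sort=True)
        .head(1)
    )
    genes_total = panel["gene_id"].nunique()
    genes_seg = retained["gene_id"].nunique()
    return {
        "assayed": int(len(panel)),
        "score_pass": int(score_ok.sum()),
        "retained": int(len(retained)),
        "retained_pct": percent(len(retained), len(panel)),
        "genes_assayed": int(genes_total),
        "genes_with_segregating": int(genes_seg),
        "genes_pct": percent(genes_seg, genes_total),
        "per_source": per_source,
        "selected_for_mapping": selected.reset_index(drop=True),
    }


# ---------------------------------------------------------------------------
# map summaries
# ---------------------------------------------------------------------------

@dataclass
class MapSummary:
    map_id: str
    positioned: int
    n_groups: int
    length_cM: float
    density_cM_per_marker: float
    unlinked: int
    distorted: int


def map_summary(spec: LinkageMapSpec, unlinked: int = 0, distorted: int = 0) -> MapSummary:
    """Positioned markers, group count, total Kosambi length and density.

    Average density is total length / positioned markers, rounded to one
    decimal (e.g. 2,086.8 cM over 1,301 markers -> 1.6 cM per marker).
    """
    if spec.n_markers == 0:
        raise ValueError("empty map")
    length = spec.total_length
    return MapSummary(
        map_id=spec.map_id,
        positioned=spec.n_markers,
        n_groups=len(spec.groups),
        length_cM=round_half_up(length, 1),
        density_cM_per_marker=round_half_up(length / spec.n_markers, 1),
        unlinked=unlinked,
        distorted=distorted,
    )


def map_density(length_cM: float, n_markers: int) -> float:
    """Average map density from printed length and marker count."""
    if n_markers <= 0:
        raise ValueError("marker count must be positive")
    return round_half_up(length_cM / n_markers, 1)


def colinearity_percent(same_order: int, shared: int) -> float:
    """Printed colinearity percentage (one decimal, half-up)."""
    if shared == 0:
        return 0.0
    return round_half_up(100.0 * same_order / shared, 1)


# ---------------------------------------------------------------------------
# consolidated report
# ---------------------------------------------------------------------------

def results_report(
    qtl_table: pd.DataFrame,
    stability: pd.DataFrame | None = None,
    coloc_table: pd.DataFrame | None = None,
    map_summaries: list[MapSummary] | None = None,
    colinearity: dict[str, dict] | None = None,
) -> dict:
    """Counts, shares and ranges over all detected single QTLs.

    Mirrors the headline tabulation: per-trait and per-class QTL counts,
    the per-population share of the total, PPVE ranges per trait, and the
    per-parent PPVE sum at maximum LOD; stability, co-location and map
    summaries are appended when given.  All shares are integer-rounded
    percentages that recompute exactly from the counts also reported.
    """
    rep: dict = {"n_qtls_total": int(len(qtl_table))}
    by_trait = {}
    for trait, sub in qtl_table.groupby("trait"):
        entry = {
            "n": int(len(sub)),
            "by_class": {k: int(v) for k, v in sub["class"].value_counts().items()},
        }
        if len(sub):
            entry["ppve_min_pct"] = round_half_up(float(sub["PPVE_pct"].min()), 1)
            entry["ppve_max_pct"] = round_half_up(float(sub["PPVE_pct"].max()), 1)
        by_trait[trait] = entry
    rep["by_trait"] = by_trait
    by_pop = {}
    for pop, sub in qtl_table.groupby("population"):
        by_pop[str(pop)] = {"n": int(len(sub)),
                            "share_pct": percent(len(sub), len(qtl_table))}
    rep["by_population"] = by_pop
    ppve_sums = {}
    for (pop, parent, trait), sub in qtl_table.groupby(["population", "parent", "trait"]):
        ppve_sums[f"{pop}_{parent}_{trait}"] = round_half_up(float(sub["PPVE_pct"].sum()), 1)
    rep["ppve_sum_at_max_lod"] = ppve_sums
    if stability is not None and len(stability):
        rep["stability"] = stability.to_dict(orient="records")
    if coloc_table is not None and len(coloc_table):
        rep["colocation"] = coloc_table.to_dict(orient="records")
    if map_summaries:
        rep["maps"] = [vars(s) for s in map_summaries]
    if colinearity:
        rep["colinearity"] = colinearity
    return rep


def report_text(rep: dict) -> str:
    """Human-readable rendering of :func:`results_report` output."""
    lines = [f"Single QTLs detected: {rep['n_qtls_total']}"]
    for trait, e in rep.get("by_trait", {}).items():
        cls = ", ".join(f"{k}={v}" for k, v in sorted(e["by_class"].items()))
        rng = (f"; PPVE {e['ppve_min_pct']}-{e['ppve_max_pct']}%"
               if "ppve_min_pct" in e else "")
        lines.append(f"  {trait}: {e['n']} ({cls}){rng}")
    for pop, e in rep.get("by_population", {}).items():
        lines.append(f"  population {pop}: {e['n']} QTLs ({e['share_pct']}% of total)")
    for s in rep.get("maps", []):
        lines.append(
            f"  map {s['map_id']}: {s['positioned']} markers, {s['n_groups']} groups, "
            f"{s['length_cM']} cM, {s['density_cM_per_marker']} cM/marker"
        )
    for key, st in rep.get("colinearity", {}).items():
        lines.append(f"  colinearity {key}: {st['same_order']}/{st['shared']} ({st['percent']}%)")
    for row in rep.get("stability", []):
        lines.append(
            f"  {row['trait']}: {row['n_clusters']} clusters, "
            f"{row['pop_replicated_pct']}% population-replicated, "
            f"{row['year_replicated_pct']}% year-replicated, "
            f"{row['env_replicated_pct']}% environment-replicated"
        )
    for row in rep.get("colocation", []):
        lines.append(
            f"  co-location {row['trait_pair']}: observed {row['observed']:.3f}, "
            f"1-P {row['one_minus_p']:.3f}, significant={row['significant']}"
        )
    return "\n".join(lines)
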