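"""End-to-end comparative QTL pipeline: simulate -> map -> PCA -> scan ->
project -> cluster -> co-locate -> report.

The pipeline reproduces the study design on synthetic data: two unrelated
full-sib families segregating for (different subsets of) one species map,
clonally replicated progeny phenotyped for bud flush, bud set and height
over multiple years in outdoor (VES) and controlled indoor (AAFC) blocks.
Each stage writes its artifacts as TSV/JSON under the output directory and
logs to a JSON-lines file; a rerun with the same configuration is
bit-identical.
"""

from __future__ import annotations

import itertools
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import coloc as coloc_mod
from . import io as io_mod
from . import pheno, project, report, scan, simulate
from .linkage import ANCHOR, MATERNAL, PATERNAL, LinkageMapSpec, build_parental_map, colinearity_stats, merge_maps
from .simulate import FLUSH, HEIGHT, SET, SITES, PlantedQtl, TrialDesign, TrueMapConfig

TRAITS = (FLUSH, SET, HEIGHT)


def _child_seeds(master: int, n: int) -> list[int]:
    """Deterministic per-component seeds below 2^31 from one master seed."""
    rng = np.random.default_rng(master)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _map_config(cfg: dict, seed: int) -> TrueMapConfig:
    m = cfg.get("map", {})
    n_groups = int(m.get("n_groups", 12))
    length = float(m.get("group_length", 175.0))
    markers = int(m.get("markers_per_group", 40))
    mix = tuple(m.get("class_mix", (0.35, 0.35, 0.30)))
    return TrueMapConfig(
        n_groups=n_groups,
        group_lengths=(length,) * n_groups,
        markers_per_group=markers,
        class_mix=mix,
        seed=seed,
    )


def _design(cfg: dict, pop_cfg: dict) -> TrialDesign:
    kw = dict(cfg.get("design", {}))
    kw["n_progeny"] = int(pop_cfg["n_progeny"])
    kw["years"] = tuple(int(y) for y in pop_cfg.get("years", (2004, 2005)))
    if "repeatability" in kw:
        kw["repeatability"] = {k: float(v) for k, v in kw["repeatability"].items()}
    return TrialDesign(**kw)


def _subset_markers(true_map: pd.DataFrame, keep_frac: float, seed: int) -> pd.DataFrame:
    """Each cross genotypes its own marker subset; anchors are always kept so
    maps remain mergeable."""
    if keep_frac >= 1.0:
        return true_map
    rng = np.random.default_rng(seed)
    keep = (rng.random(len(true_map)) < keep_frac) | (true_map["seg_class"] == ANCHOR).to_numpy()
    return true_map[keep].reset_index(drop=True)


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Run every stage from one configuration; returns the artifact bundle.

    ``config`` is a YAML path or an equivalent dict; see configs/small.yaml
    for the schema.  Missing simulate inputs are a configuration error.
    """
    if not isinstance(config, dict):
        config = io_mod.load_config(config)
    if "populations" not in config:
        raise ValueError("config error: no 'populations' simulate block and no input paths")
    outdir = Path(outdir or config.get("out", "results/run"))
    outdir.mkdir(parents=True, exist_ok=True)
    log = io_mod.JsonLogger(outdir / "log.jsonl")
    master = int(config.get("seed", 0))
    seeds = _child_seeds(master, 64)
    scan_cfg = config.get("scan", {})
    step = float(scan_cfg.get("step", 1.0))
    n_perm = int(scan_cfg.get("n_perm", 1000))
    alpha = float(scan_cfg.get("alpha", 0.05))
    reporting = bool(scan_cfg.get("reporting", n_perm >= 1000))
    coloc_cfg = config.get("coloc", {})

    # ---- simulate ---------------------------------------------------------
    map_cfg = _map_config(config, seeds[0])
    species_map = simulate.simulate_parents_and_map(map_cfg)
    keep_frac = float(config.get("marker_keep_frac", 0.8))
    crosses: dict[str, simulate.SimulatedCross] = {}
    shared_design = _design(config, next(iter(config["populations"].values())))
    qtls = config.get("qtls", "default")
    if qtls == "default":
        qtl_list = simulate.default_planted_qtls(species_map, shared_design,
                                                 np.random.default_rng(seeds[1]))
    else:
        qtl_list = [PlantedQtl(**q) for q in qtls]
    for i, (pop, pop_cfg) in enumerate(sorted(config["populations"].items())):
        design = _design(config, pop_cfg)
        cross_map = _subset_markers(species_map, keep_frac, seeds[2 + i])
        cross = simulate.simulate_cross(
            pop, None, design, seeds[10 + i], qtls=qtl_list, true_map=cross_map,
            missing_rate=float(config.get("missing_rate", 0.005)),
        )
        crosses[pop] = cross
        io_mod.write_genotypes(cross.genotypes.maternal, outdir / f"genotypes_{pop}_maternal.tsv")
        io_mod.write_genotypes(cross.genotypes.paternal, outdir / f"genotypes_{pop}_paternal.tsv")
        io_mod.write_phenology(cross.phenology, outdir / f"phenology_{pop}.tsv")
        io_mod.write_heights(cross.heights, outdir / f"heights_{pop}.tsv")
        io_mod.write_truth(cross.truth, outdir / f"truth_{pop}.json")
        log.log("simulate", population=pop, n_progeny=design.n_progeny,
                n_markers=len(cross_map), seed=seeds[10 + i])

    # ---- linkage maps -----------------------------------------------------
    parent_maps: dict[tuple[str, str], LinkageMapSpec] = {}
    map_reports: dict[str, dict] = {}
    summaries = []
    colinearity: dict[str, dict] = {}
    sub_composites = []
    for pop, cross in crosses.items():
        seg = dict(zip(cross.true_map["marker"], cross.true_map["seg_class"]))
        for parent, table in ((MATERNAL, cross.genotypes.maternal),
                              (PATERNAL, cross.genotypes.paternal)):
            spec, rep = build_parental_map(table, f"{pop}_{parent}", seg_classes=seg)
            parent_maps[(pop, parent)] = spec
            map_reports[spec.map_id] = rep
            summaries.append(report.map_summary(spec, unlinked=len(rep["unlinked"]),
                                                distorted=len(rep["distorted"])))
            io_mod.write_map(spec, outdir / f"map_{spec.map_id}.tsv")
            log.log("map", map_id=spec.map_id, **{k: v for k, v in rep.items()
                                                  if not isinstance(v, list)})
        col = colinearity_stats(parent_maps[(pop, MATERNAL)], parent_maps[(pop, PATERNAL)])
        colinearity[f"{pop}_maternal_vs_paternal"] = col
        sub, sub_rep = merge_maps(
            [parent_maps[(pop, MATERNAL)], parent_maps[(pop, PATERNAL)]],
            map_id=f"subcomposite_{pop}", kind="sub-composite")
        sub_composites.append(sub)
        io_mod.write_map(sub, outdir / f"map_subcomposite_{pop}.tsv")
    composite, comp_rep = merge_maps(sub_composites, map_id="composite", kind="composite")
    summaries.append(report.map_summary(composite))
    io_mod.write_map(composite, outdir / "map_composite.tsv")
    log.log("composite", n_markers=composite.n_markers, length=composite.total_length,
            warnings=len(comp_rep["warnings"]))

    # ---- composite phenotypes --------------------------------------------
    components: list[pheno.CompositePhenotype] = []
    comp_rows = []
    for pop, cross in crosses.items():
        years = sorted(cross.phenology["year"].unique())
        for trait, site, year in itertools.product((FLUSH, SET), SITES, years):
            mat = pheno.build_stage_matrix(cross.phenology, trait, site, year)
            comps = pheno.pca_composite(mat, trait=trait, site=site,
                                        population=pop, year=year)
            components.extend(comps)
            for c in comps:
                comp_rows.append({
                    "population": pop, "trait": trait, "site": site, "year": year,
                    "pc": c.pc, "eigenvalue": round(c.eigenvalue, 3),
                    "pct_variance": round(c.pct_variance, 1),
                    "dominant_stages": ";".join(c.dominant_stages),
                    "normal": c.normal,
                })
    io_mod.write_table(pd.DataFrame(comp_rows), outdir / "composite_phenotypes.tsv")
    log.log("pca", n_components=len(components))

    # ---- QTL scans --------------------------------------------------------
    records: list[scan.QtlRecord] = []
    threshold_rows = []
    scan_seed = itertools.count(seeds[30])
    for pop, cross in crosses.items():
        datasets: list[tuple[str, dict, pd.Series]] = []
        years = sorted(cross.heights["year"].unique())
        for site, year in itertools.product(SITES, years):
            resp = scan.phenotype_for_scan(heights=cross.heights, site=site, year=year)
            ctx = {"trait": HEIGHT, "population": pop, "site": site, "year": year, "pc": None}
            datasets.append((f"{HEIGHT}_{pop}_{site}_{year}", ctx, resp))
        for c in components:
            if c.population != pop:
                continue
            resp = scan.phenotype_for_scan(composite=c)
            ctx = {"trait": c.trait, "population": pop, "site": c.site,
                   "year": c.year, "pc": c.pc}
            datasets.append((c.dataset_id, ctx, resp))
        for parent in (MATERNAL, PATERNAL):
            mspec = parent_maps[(pop, parent)]
            geno = cross.genotypes.maternal if parent == MATERNAL else cross.genotypes.paternal
            for dataset_id, ctx, resp in datasets:
                sd = next(scan_seed) % (2**31)
                chrom_thr, genome_thr = scan.permutation_thresholds(
                    mspec, geno, resp, n_perm=n_perm, alpha=alpha, seed=sd,
                    step=step, reporting=reporting)
                profiles = scan.genome_scan(mspec, geno, resp, step=step,
                                            dataset=f"{dataset_id}_{parent}")
                for grp, (profile, stats_) in profiles.items():
                    rec = scan.classify_qtl(
                        profile, stats_, chrom_thr[grp].threshold, genome_thr.threshold,
                        context={**ctx, "parent": parent})
                    if rec.qtl_class == scan.INDICATIVE:
                        # a candidate needs a real peak: near the suggestive
                        # threshold, with a support interval that actually
                        # localises (not a flat-profile artefact)
                        span = mspec.group_length(grp)
                        width = rec.ci1[1] - rec.ci1[0]
                        if rec.lod < 0.8 * chrom_thr[grp].threshold or width > 0.5 * span:
                            continue
                    records.append(rec)
                threshold_rows.append({
                    "dataset": dataset_id, "parent": parent, "scope": "genome",
                    "group": "", "threshold": round(genome_thr.threshold, 3),
                    "n_perm": n_perm, "seed": sd,
                })
    qtl_table = io_mod.qtl_records_to_frame(records)
    io_mod.write_table(qtl_table, outdir / "qtl_scan_all_peaks.tsv")
    io_mod.write_table(pd.DataFrame(threshold_rows), outdir / "thresholds.tsv")
    log.log("scan", n_profiles=len(records))

    # ---- projection, retention, clusters ----------------------------------
    projected_all: list[dict] = []
    unprojected = 0
    for (pop, parent), mspec in parent_maps.items():
        frames = project.build_anchor_frames(mspec, composite)
        recs = [r for r in records if r.population == pop and r.parent == parent]
        projected, failed = project.project_records(recs, frames)
        projected_all.extend(projected)
        unprojected += len(failed)
    significant = [r for r in projected_all if r["qtl_class"] == scan.SIGNIFICANT]
    suggestive = [r for r in projected_all if r["qtl_class"] == scan.SUGGESTIVE]
    candidates = [r for r in projected_all if r["qtl_class"] == scan.INDICATIVE]
    retained = scan.retain_indicative(candidates, significant)
    final = significant + suggestive + retained
    log.log("project", projected=len(projected_all), unprojected=unprojected,
            significant=len(significant), suggestive=len(suggestive),
            indicative_retained=len(retained))

    clusters_by_trait: dict[str, list[project.QtlCluster]] = {}
    for trait in TRAITS:
        sub = [r for r in final if r["trait"] == trait]
        clusters_by_trait[trait] = project.consolidate_clusters(sub, composite) if sub else []
    cluster_frame = project.clusters_to_frame(clusters_by_trait)
    io_mod.write_table(cluster_frame, outdir / "qtl_clusters.tsv")
    stability = project.stability_table(clusters_by_trait)
    io_mod.write_table(stability, outdir / "stability.tsv")

    final_frame = pd.DataFrame(final)
    if len(final_frame):
        final_frame[["ci1_lo", "ci1_hi"]] = pd.DataFrame(final_frame.pop("ci1").tolist(),
                                                         index=final_frame.index)
        final_frame[["ci2_lo", "ci2_hi"]] = pd.DataFrame(final_frame.pop("ci2").tolist(),
                                                         index=final_frame.index)
    io_mod.write_table(final_frame, outdir / "qtl_projected.tsv")

    # ---- co-location ------------------------------------------------------
    coloc_rows = []
    drop = int(coloc_cfg.get("drop", 1))
    n_rand = int(coloc_cfg.get("n", 1000))
    for i, (t1, t2) in enumerate(itertools.combinations(TRAITS, 2)):
        coloc_rows.extend(coloc_mod.cluster_pair_tests(
            composite, clusters_by_trait[t1], clusters_by_trait[t2],
            (t1, t2), n=n_rand, seed=seeds[50 + i], drop=drop))
    coloc_table = pd.DataFrame(coloc_rows, columns=[
        "trait_pair", "group", "cluster_a", "cluster_b", "n_intervals",
        "observed", "null_mean", "exceedance", "one_minus_p", "significant",
        "n_perm", "seed"])
    io_mod.write_table(coloc_table, outdir / "colocation.tsv")
    log.log("coloc", n_pairs=len(coloc_rows))

    # ---- report -----------------------------------------------------------
    rep = report.results_report(
        qtl_table=final_frame.rename(columns={"ppve_pct": "PPVE_pct",
                                              "qtl_class": "class"})
        if len(final_frame) else pd.DataFrame(columns=["trait", "population", "parent",
                                                       "PPVE_pct", "class"]),
        stability=stability, coloc_table=coloc_table,
        map_summaries=summaries, colinearity=colinearity)
    io_mod.write_truth(rep, outdir / "report.json")
    (outdir / "report.txt").write_text(report.report_text(rep) + "\n")
    log.log("report", n_qtls=rep["n_qtls_total"])

    return {
        "crosses": crosses,
        "parent_maps": parent_maps,
        "composite": composite,
        "components": components,
        "records": records,
        "projected": projected_all,
        "final": final,
        "clusters": clusters_by_trait,
        "stability": stability,
        "coloc": coloc_table,
        "report": rep,
        "outdir": outdir,
    }
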