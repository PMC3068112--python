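"""Calibration and recovery experiments over the simulator.

These are the package's own validation studies: familywise error of the
genome-wide permutation threshold under the null, size of the co-location
randomization test under its own null generator, detection rate and
support-interval coverage for a planted QTL of known effect (including the
small-sample PPVE inflation known as the Beavis effect), projection
accuracy through rebuilt maps, and end-to-end co-location power for a
pleiotropic locus versus independent loci.  Problem sizes are arguments so
drivers can choose replicate counts; defaults are desk-scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import coloc as coloc_mod
from . import project, scan, simulate
from .linkage import MATERNAL, LinkageMapSpec, build_parental_map
from .simulate import PlantedQtl, TrialDesign, TrueMapConfig


def _testcross_map(n_groups: int, length: float, markers: int, seed: int) -> pd.DataFrame:
    cfg = TrueMapConfig(
        n_groups=n_groups, group_lengths=(length,) * n_groups,
        markers_per_group=markers, class_mix=(1.0, 0.0, 0.0), seed=seed,
    )
    return simulate.simulate_parents_and_map(cfg)


def _direct_response(
    geno: pd.DataFrame, marker: str | None, beta: float, rng: np.random.Generator
) -> pd.Series:
    """Unit-variance response with an optional additive marker effect."""
    y = rng.normal(0.0, 1.0, len(geno))
    if marker is not None:
        y = y + beta * (geno[marker].to_numpy() - 0.5)
    return pd.Series(y, index=geno.index)


def beta_for_ppve(ppve_percent: float) -> float:
    """Effect on a unit-variance residual giving the target variance share."""
    v = ppve_percent / 100.0
    return float(2.0 * np.sqrt(v / (1.0 - v)))


# ---------------------------------------------------------------------------
# familywise error of the genome-wide threshold
# ---------------------------------------------------------------------------

def genome_fwer(
    n_sims: int = 500,
    n_perm: int = 200,
    n_progeny: int = 150,
    n_groups: int = 3,
    markers_per_group: int = 10,
    group_length: float = 100.0,
    step: float = 2.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null simulations whose maximum LOD exceeds the
    genome-wide permutation threshold (should sit near alpha)."""
    tmap = _testcross_map(n_groups, group_length, markers_per_group, seed)
    mspec = simulate.true_map_spec(tmap, MATERNAL)
    rng = np.random.default_rng(seed + 1)
    hits = 0
    for s in range(n_sims):
        geno = simulate.simulate_progeny(tmap, n_progeny, seed + 10 + s, missing_rate=0.0)
        y = _direct_response(geno.maternal, None, 0.0, rng)
        _, genome = scan.permutation_thresholds(
            mspec, geno.maternal, y, n_perm=n_perm, alpha=alpha,
            seed=seed + 20000 + s, step=step, reporting=False)
        profiles = scan.genome_scan(mspec, geno.maternal, y, step=step)
        max_lod = max(p.peak_lod for p, _ in profiles.values())
        hits += max_lod >= genome.threshold
    return hits / n_sims


# ---------------------------------------------------------------------------
# co-location test size under its own null
# ---------------------------------------------------------------------------

def _null_intervals(
    composite: LinkageMapSpec, widths: np.ndarray, rng: np.random.Generator
) -> list[tuple[str, float, float]]:
    groups = composite.groups
    lengths = np.array([composite.group_length(g) for g in groups])
    out = []
    for w in widths:
        feasible = np.nonzero(lengths >= w)[0]
        p = lengths[feasible] / lengths[feasible].sum()
        gi = rng.choice(feasible, p=p)
        lo = rng.uniform(0.0, lengths[gi] - w)
        out.append((groups[gi], float(lo), float(lo + w)))
    return out


def coloc_null_rejection_rate(
    n_runs: int = 500,
    n_perm: int = 200,
    n_groups: int = 12,
    group_length: float = 175.0,
    n_intervals: int = 10,
    seed: int = 0,
) -> float:
    """Rejection rate of the co-location test when both traits' intervals
    are drawn from the randomization null itself (should sit near 0.05)."""
    df = pd.DataFrame({
        "group": [simulate.roman(i + 1) for i in range(n_groups) for _ in (0, 1)],
        "marker": [f"m{i}_{j}" for i in range(n_groups) for j in (0, 1)],
        "position_cM": [p for _ in range(n_groups) for p in (0.0, group_length)],
    })
    composite = LinkageMapSpec("null", "composite", df)
    rng = np.random.default_rng(seed)
    rejections = 0
    for run in range(n_runs):
        widths_a = rng.uniform(8.0, 30.0, n_intervals)
        widths_b = rng.uniform(8.0, 30.0, n_intervals)
        iv_a = _null_intervals(composite, widths_a, rng)
        iv_b = _null_intervals(composite, widths_b, rng)
        res = coloc_mod.colocation_test(
            composite, iv_a, iv_b, ("a", "b"), n=n_perm, seed=seed + 1000 + run)
        rejections += res.significant
    return rejections / n_runs


def coloc_toy_null_mean(n: int = 100000, seed: int = 0) -> float:
    """Mean null overlap proportion for two length-2 intervals on a single
    100-to-10 cM group (analytic value 0.4375)."""
    df = pd.DataFrame({"group": ["I", "I"], "marker": ["x", "y"], "position_cM": [0.0, 10.0]})
    composite = LinkageMapSpec("toy", "composite", df)
    null = coloc_mod.randomize_intervals(
        composite, [("I", 0.0, 2.0)], [("I", 0.0, 2.0)], n=n, seed=seed)
    return float(null.mean())


# ---------------------------------------------------------------------------
# planted-QTL recovery (detection, coverage, Beavis direction)
# ---------------------------------------------------------------------------

def qtl_recovery(
    n_reps: int = 200,
    n_progeny: int = 500,
    ppve_percent: float = 10.0,
    n_perm: int = 200,
    n_groups: int = 3,
    markers_per_group: int = 10,
    group_length: float = 100.0,
    step: float = 2.0,
    seed: int = 0,
) -> dict:
    """Detection rate, -2 LOD coverage and mean estimated PPVE of a planted
    QTL at a marker position, over replicate crosses.

    Detection = the QTL group's peak exceeds at least the chromosome-wise
    threshold.  Estimated PPVE is recorded for detected replicates only, so
    small samples show the upward selection bias (Beavis effect).
    """
    tmap = _testcross_map(n_groups, group_length, markers_per_group, seed)
    mspec = simulate.true_map_spec(tmap, MATERNAL)
    target_group = mspec.groups[0]
    posn = mspec.group_positions(target_group)
    qtl_marker = posn.index[len(posn) // 2]
    qtl_pos = float(posn[qtl_marker])
    beta = beta_for_ppve(ppve_percent)
    rng = np.random.default_rng(seed + 5)
    detected = 0
    covered = 0
    ppve_detected: list[float] = []
    for rep in range(n_reps):
        geno = simulate.simulate_progeny(tmap, n_progeny, seed + 100 + rep, missing_rate=0.0)
        y = _direct_response(geno.maternal, qtl_marker, beta, rng)
        chrom, genome = scan.permutation_thresholds(
            mspec, geno.maternal, y, n_perm=n_perm, seed=seed + 40000 + rep,
            step=step, reporting=False)
        profile, stats_ = scan.interval_scan(
            posn, geno.maternal, y, step=step, group=target_group)
        if profile.peak_lod >= chrom[target_group].threshold:
            detected += 1
            lo, hi = scan.support_interval(profile, 2.0)
            covered += lo <= qtl_pos <= hi
            ppve_detected.append(stats_["ppve_pct"])
    return {
        "n_reps": n_reps,
        "n_progeny": n_progeny,
        "ppve_planted_pct": ppve_percent,
        "detection_rate": detected / n_reps,
        "ci2_coverage": covered / detected if detected else np.nan,
        "mean_ppve_detected_pct": float(np.mean(ppve_detected)) if ppve_detected else np.nan,
    }


# ---------------------------------------------------------------------------
# projection accuracy through rebuilt maps
# ---------------------------------------------------------------------------

def projection_accuracy(
    n_reps: int = 20,
    n_progeny: int = 300,
    tolerance_cM: float = 5.0,
    seed: int = 0,
) -> float:
    """Share of replicates in which a peak position projected from a
    rebuilt (noisy) parental map lands within ``tolerance_cM`` of its true
    composite position."""
    cfg = TrueMapConfig(n_groups=2, group_lengths=(100.0, 100.0),
                        markers_per_group=14, class_mix=(0.5, 0.0, 0.5), seed=seed)
    tmap = simulate.simulate_parents_and_map(cfg)
    truth = simulate.true_map_spec(tmap)  # the reference composite frame
    seg = dict(zip(tmap["marker"], tmap["seg_class"]))
    sub = tmap[tmap["group"] == "I"]
    true_pos = float(sub["position_cM"].iloc[len(sub) // 2])
    ok = 0
    for rep in range(n_reps):
        geno = simulate.simulate_progeny(tmap, n_progeny, seed + 7 + rep, missing_rate=0.005)
        mspec, _ = build_parental_map(geno.maternal, "mat", seg_classes=seg)
        frames = project.build_anchor_frames(mspec, truth)
        # locate the same physical point on the rebuilt map: use the nearest
        # true marker that was positioned, then its rebuilt coordinate
        placed = mspec.df.set_index("marker")
        cands = [(abs(p - true_pos), m) for m, p in zip(sub["marker"], sub["position_cM"])
                 if m in placed.index and seg[m] in (MATERNAL, "anchor")]
        _, marker = min(cands)
        grp = placed.loc[marker, "group"]
        if grp not in frames:
            continue
        proj = project.project_position(float(placed.loc[marker, "position_cM"]), frames[grp])
        true_marker_pos = float(sub.set_index("marker").loc[marker, "position_cM"])
        ok += abs(proj - true_marker_pos) <= tolerance_cM
    return ok / n_reps


# ---------------------------------------------------------------------------
# end-to-end co-location power / size
# ---------------------------------------------------------------------------

def pleiotropy_experiment(
    n_reps: int = 100,
    pleiotropic: bool = True,
    n_progeny: int = 300,
    ppve_percent: float = 15.0,
    n_perm: int = 150,
    n_rand: int = 200,
    seed: int = 0,
) -> float:
    """Rate at which the co-location test flags two traits as co-located.

    Each replicate simulates a cross, rebuilds the maternal map from the
    genotypes, scans both traits, projects the detected QTLs' -1 LOD
    intervals onto the true map through shared-marker anchor frames, and
    runs the interval-randomization test.  With ``pleiotropic=True`` the two
    traits share one causal locus (plus one private locus each); otherwise
    all loci sit on different groups.
    """
    cfg = TrueMapConfig(n_groups=6, group_lengths=(100.0,) * 6,
                        markers_per_group=10, class_mix=(0.6, 0.0, 0.4), seed=seed)
    tmap = simulate.simulate_parents_and_map(cfg)
    truth = simulate.true_map_spec(tmap)
    seg = dict(zip(tmap["marker"], tmap["seg_class"]))
    mspec_true = simulate.true_map_spec(tmap, MATERNAL)

    def marker_on(group: str) -> str:
        posn = mspec_true.group_positions(group)
        return posn.index[len(posn) // 2]

    # each trait is measured in two replicate datasets (as across years), so a
    # real co-location contributes several mutually overlapping intervals
    trait_marker = {"a": marker_on("I"), "b": marker_on("I" if pleiotropic else "III")}
    n_datasets = 2
    beta = beta_for_ppve(ppve_percent)
    rng = np.random.default_rng(seed + 3)
    flagged = 0
    for rep in range(n_reps):
        geno = simulate.simulate_progeny(tmap, n_progeny, seed + 50 + rep, missing_rate=0.0)
        gm = geno.maternal
        mspec, _ = build_parental_map(gm, "mat", seg_classes=seg)
        frames = project.build_anchor_frames(mspec, truth)
        intervals: dict[str, list[tuple[str, float, float]]] = {"a": [], "b": []}
        for trait, mk in trait_marker.items():
            for ds in range(n_datasets):
                y = pd.Series(
                    beta * (gm[mk].to_numpy() - 0.5) + rng.normal(0.0, 1.0, len(gm)),
                    index=gm.index)
                chrom, genome = scan.permutation_thresholds(
                    mspec, gm, y, n_perm=n_perm,
                    seed=seed + 90000 + 4 * rep + 2 * ds + (trait == "b"),
                    step=2.0, reporting=False)
                profiles = scan.genome_scan(mspec, gm, y, step=2.0, dataset=f"{trait}{ds}")
                for grp, (profile, stats_) in profiles.items():
                    if profile.peak_lod < chrom[grp].threshold or grp not in frames:
                        continue
                    rec = scan.classify_qtl(profile, stats_, chrom[grp].threshold,
                                            genome.threshold, {"trait": trait})
                    proj = project.project_qtl(rec, frames[grp])
                    intervals[trait].append((proj["group"], *proj["ci1"]))
        if not intervals["a"] or not intervals["b"]:
            continue
        res = coloc_mod.colocation_test(truth, intervals["a"], intervals["b"],
                                        ("a", "b"), n=n_rand, seed=seed + 70000 + rep)
        flagged += res.significant
    return flagged / n_reps
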