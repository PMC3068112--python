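"""Composite phenology phenotypes and quantitative-trait statistics.

Ordinal bud-development scores recorded on a visit calendar are converted
to the Julian day on which each stage was first reached (one row per tree,
one column per stage).  A principal component analysis of the covariance
matrix of these day-to-stage rows, with Kaiser retention (eigenvalue > 1)
and an optional varimax rotation, compresses the multi-stage record into
one to three quantitative composite phenotypes whose per-tree factorial
scores feed the QTL scans.

Also here: a Lilliefors-corrected Kolmogorov-Smirnov normality gate, the
normality-gated Pearson/Spearman trait correlation, and clonal
repeatability from one-way variance components.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.multivariate.factor_rotation import rotate_factors

from .simulate import FLUSH, N_STAGES, julian_day


# ---------------------------------------------------------------------------
# day-to-stage conversion
# ---------------------------------------------------------------------------

def day_to_stage(days: np.ndarray, stages: np.ndarray, n_stages: int) -> np.ndarray:
    """Julian day each stage 1..n_stages was first reached for one tree-year.

    day(s) is the earliest observation date whose recorded stage is >= s, so
    stages skipped between visits inherit the first date at or after them.
    A locally decreasing stage sequence (scoring noise) is repaired with a
    cumulative maximum; stages never reached are NaN.
    """
    days = np.asarray(days, dtype=float)
    stages = np.asarray(stages, dtype=float)
    order = np.argsort(days, kind="stable")
    days, stages = days[order], stages[order]
    if np.any(np.diff(stages) < 0):
        _warnings.warn("decreasing stage sequence; keeping cumulative maximum")
        stages = np.maximum.accumulate(stages)
    out = np.full(n_stages, np.nan)
    for s in range(1, n_stages + 1):
        hit = np.nonzero(stages >= s)[0]
        if hit.size:
            out[s - 1] = days[hit[0]]
    return out


def build_stage_matrix(
    phenology: pd.DataFrame,
    trait: str,
    site: str,
    year: int,
    block_mean: bool = True,
) -> pd.DataFrame:
    """Day-to-stage matrix for one trait x site x year dataset.

    Rows are trees; cells are the per-tree mean (over the site's ramets, one
    per block) of the Julian day each stage was reached.  Trees missing more
    than half of the stage columns are dropped.
    """
    sub = phenology[
        (phenology["trait"] == trait)
        & (phenology["site"] == site)
        & (phenology["year"] == int(year))
    ]
    if sub.empty:
        raise ValueError(f"no observations for {trait}/{site}/{year}")
    n_stages = N_STAGES[trait]
    if "julian_day" in sub.columns:
        jd = sub["julian_day"].to_numpy()
    else:
        jd = julian_day(sub["date"])
    sub = sub.assign(_jd=jd)
    rows = {}
    for (tree, ramet), obs in sub.groupby(["tree_id", "ramet"], sort=False):
        rows[(tree, ramet)] = day_to_stage(obs["_jd"].to_numpy(), obs["stage"].to_numpy(), n_stages)
    mat = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=[f"stage_{s}" for s in range(1, n_stages + 1)])
    mat.index = pd.MultiIndex.from_tuples(mat.index, names=["tree_id", "ramet"])
    if block_mean:
        mat = mat.groupby(level="tree_id").mean()
    keep = mat.notna().mean(axis=1) > 0.5
    return mat[keep]


# ---------------------------------------------------------------------------
# covariance PCA with Kaiser retention
# ---------------------------------------------------------------------------

@dataclass
class CompositePhenotype:
    """One retained component of a day-to-stage matrix."""

    trait: str
    site: str
    population: str
    year: int
    pc: int  # 1-based component index
    eigenvalue: float
    pct_variance: float
    loadings: pd.Series = field(repr=False)
    dominant_stages: list[str] = field(default_factory=list)
    scores: pd.Series = field(default=None, repr=False)
    normal: bool | None = None

    @property
    def dataset_id(self) -> str:
        return f"{self.trait}_{self.population}_{self.site}_{self.year}_PC{self.pc}"


def pca_composite(
    matrix: pd.DataFrame,
    trait: str = "",
    site: str = "",
    population: str = "",
    year: int = 0,
    kaiser: float = 1.0,
    max_components: int = 3,
    rotate: bool = True,
    dominant_frac: float = 0.9,
) -> list[CompositePhenotype]:
    """Eigendecompose the pairwise-complete covariance of a stage matrix.

    Components with eigenvalue strictly greater than ``kaiser`` are retained
    (at most ``max_components``); a varimax rotation is applied when two or
    more components survive.  Percent variance is eigenvalue / trace x 100;
    the dominant stage range collects stages whose |loading| is at least
    ``dominant_frac`` of the component's largest |loading|.  Factorial
    scores are the centred rows projected on the (rotated) directions, with
    missing cells treated as the column mean.
    """
    mat = matrix.copy()
    variances = mat.var(ddof=1)
    dead = variances[(variances.isna()) | (variances == 0.0)].index
    if len(dead):
        mat = mat.drop(columns=dead)
    if mat.shape[1] < 2 or mat.shape[0] < 3:
        return []
    if mat.shape[0] < mat.shape[1]:
        _warnings.warn("fewer units than stage columns; covariance is rank-deficient")
    cov = mat.cov()  # pairwise complete, ddof=1
    vals, vecs = np.linalg.eigh(cov.to_numpy())
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    trace = float(np.trace(cov.to_numpy()))
    k = int(min((vals > kaiser + 1e-9 * max(1.0, trace)).sum(), max_components))
    if k == 0:
        return []
    vecs_k = vecs[:, :k]
    vals_k = vals[:k]
    # rotate only "when required": comparable leading components are
    # ambiguous in direction, a dominant first axis is left untouched
    if rotate and k >= 2 and vals_k[0] / max(vals_k[1], 1e-12) < 3.0:
        loadings = vecs_k * np.sqrt(vals_k)
        _, rot = rotate_factors(loadings, "varimax")
        dirs = vecs_k @ rot
        expl = np.diag(rot.T @ np.diag(vals_k) @ rot)
        order2 = np.argsort(expl)[::-1]
        dirs, expl = dirs[:, order2], expl[order2]
    else:
        dirs, expl = vecs_k, vals_k
    centred = mat - mat.mean()
    filled = centred.fillna(0.0).to_numpy()
    out = []
    for j in range(k):
        w = pd.Series(dirs[:, j], index=mat.columns)
        if w.iloc[np.argmax(np.abs(w.to_numpy()))] < 0:
            w = -w  # sign convention: dominant loading positive
        scores = pd.Series(filled @ w.to_numpy(), index=mat.index)
        amax = np.abs(w).max()
        dom = [c for c in mat.columns if abs(w[c]) >= dominant_frac * amax]
        normal = normality_gate(scores.to_numpy())[0] if len(scores) >= 20 else None
        out.append(CompositePhenotype(
            trait=trait, site=site, population=population, year=int(year),
            pc=j + 1, eigenvalue=float(expl[j]),
            pct_variance=float(100.0 * expl[j] / trace),
            loadings=w, dominant_stages=dom, scores=scores, normal=normal,
        ))
    return out


# ---------------------------------------------------------------------------
# normality gate and correlations
# ---------------------------------------------------------------------------

def normality_gate(values: np.ndarray, alpha: float = 0.05) -> tuple[bool, float, float]:
    """Kolmogorov-Smirnov test against a fitted normal (Lilliefors correction).

    Returns (normal?, statistic, p).  A constant vector is non-normal by
    convention, with no test.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 20:
        raise ValueError("normality gate needs at least 20 values")
    if np.ptp(x) == 0.0:
        return False, np.nan, 0.0
    stat, p = lilliefors(x, dist="norm")
    return bool(p >= alpha), float(stat), float(p)


def trait_correlation(x: np.ndarray, y: np.ndarray) -> dict:
    """Pearson when both vectors pass the normality gate, Spearman otherwise.

    Magnitude classes follow the 0.1 / 0.3 / 0.5 convention
    (small / medium / large).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 10:
        raise ValueError("need at least 10 complete pairs")
    try:
        both_normal = normality_gate(x)[0] and normality_gate(y)[0]
    except ValueError:  # < 20 values: fall back to the rank method
        both_normal = False
    if both_normal:
        r, p = stats.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = stats.spearmanr(x, y)
        method = "spearman"
    a = abs(r)
    size = "large" if a >= 0.5 else "medium" if a >= 0.3 else "small" if a >= 0.1 else "negligible"
    return {"coefficient": float(r), "method": method, "p": float(p), "n": int(x.size),
            "magnitude": size}


# ---------------------------------------------------------------------------
# clonal repeatability
# ---------------------------------------------------------------------------

def clonal_repeatability(values: np.ndarray, clones: np.ndarray) -> float:
    """Between-clone variance share from one-way ANOVA variance components.

    R = sigma2_clone / (sigma2_clone + sigma2_within) with the unbalanced
    n0 correction; clipped to [0, 1).  Clones with a single ramet are
    dropped; if none has two ramets it is an error.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "clone": np.asarray(clones)})
    df = df.dropna()
    sizes = df.groupby("clone")["y"].size()
    keep = sizes[sizes >= 2].index
    if len(keep) == 0:
        raise ValueError("repeatability needs clones with at least two ramets")
    if len(keep) < 20:
        _warnings.warn("fewer than 20 clones; repeatability estimate is unstable")
    df = df[df["clone"].isin(keep)]
    groups = df.groupby("clone")["y"]
    k = groups.ngroups
    n_i = groups.size().to_numpy(dtype=float)
    N = n_i.sum()
    grand = df["y"].mean()
    means = groups.mean().to_numpy()
    ss_between = float(np.sum(n_i * (means - grand) ** 2))
    ss_within = float(np.sum((df["y"] - groups.transform("mean")) ** 2))
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k)
    n0 = (N - np.sum(n_i ** 2) / N) / (k - 1)
    sigma_b = max((ms_between - ms_within) / n0, 0.0)
    r = sigma_b / (sigma_b + ms_within) if (sigma_b + ms_within) > 0 else 0.0
    return float(min(r, 1.0 - 1e-12))
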