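"""Readers and writers for the pipeline's tabular formats.

Everything is plain text: TSV for genotype, map, phenology, height, QTL,
cluster and threshold tables; JSON for truth files; YAML for run
configuration.  Genotype tables are progeny x marker with 0/1 allele-origin
codes and "NA" for missing.  All writers round-trip losslessly through
their readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .linkage import LinkageMapSpec

NA = "NA"


# --- genotypes -------------------------------------------------------------

def write_genotypes(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "tree_id"
    formatted = out.map(lambda v: NA if pd.isna(v) else str(int(v)))
    formatted.to_csv(path, sep="\t", na_rep=NA)


def read_genotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="tree_id", na_values=[NA])
    return df.astype(float)


# --- maps ------------------------------------------------------------------

def write_map(spec: LinkageMapSpec, path: str | Path) -> None:
    df = spec.df.copy()
    df.insert(0, "map_id", spec.map_id)
    df["position_cM"] = df["position_cM"].round(1)
    df.to_csv(path, sep="\t", index=False)


def read_map(path: str | Path, kind: str = "parental") -> LinkageMapSpec:
    df = pd.read_csv(path, sep="\t")
    map_id = str(df["map_id"].iloc[0]) if "map_id" in df.columns else Path(path).stem
    return LinkageMapSpec(map_id, kind, df[["group", "marker", "position_cM"]])


# --- phenotypes ------------------------------------------------------------

def write_phenology(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["tree_id", "ramet", "block", "site", "year", "date", "trait", "stage"]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, sep="\t", index=False)


def read_phenology(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_heights(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_heights(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- QTL and result tables -------------------------------------------------

def qtl_records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "dataset": r.dataset, "trait": r.trait, "population": r.population,
            "parent": r.parent, "site": r.site, "year": r.year,
            "pc": "" if r.pc is None else r.pc, "group": r.group,
            "peak_cM": r.peak_cM, "LOD": r.lod, "PPVE_pct": r.ppve_pct,
            "effect": r.effect,
            "ci1_lo": r.ci1[0], "ci1_hi": r.ci1[1],
            "ci2_lo": r.ci2[0], "ci2_hi": r.ci2[1],
            "class": r.qtl_class,
            "thr_chromosome": r.threshold_chromosome,
            "thr_genome": r.threshold_genome,
        })
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- truth / config --------------------------------------------------------

def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True, default=_jsonable)


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(list(x) if isinstance(x, tuple) else x for x in obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


class JsonLogger:
    """Structured run log: one JSON object per line."""

    def __init__(self, path: str | Path | None):
        self.path = Path(path) if path else None
        if self.path:
            self.path.write_text("")

    def log(self, stage: str, **fields) -> None:
        if not self.path:
            return
        with open(self.path, "a") as fh:
            fh.write(json.dumps({"stage": stage, **fields}, default=_jsonable) + "\n")
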