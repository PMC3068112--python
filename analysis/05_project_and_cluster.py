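"""Project single QTLs onto the composite map and consolidate clusters.

Peaks and -1/-2 LOD intervals travel through homothetic anchor frames;
indicative candidates survive only if their interval overlaps two or more
significant QTLs.  Clusters require interval overlap sharing at least one
composite-map marker; the stability table counts replication across
crosses, years and environments.
"""

import importlib
import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
cfg = importlib.import_module("00_config")

import budqtl.io as io_mod
from budqtl import project, scan
from budqtl.linkage import MATERNAL, PATERNAL
from budqtl.scan import QtlRecord


def _to_records(table: pd.DataFrame) -> list[QtlRecord]:
    recs = []
    for _, r in table.iterrows():
        recs.append(QtlRecord(
            dataset=r["dataset"], trait=r["trait"], population=r["population"],
            parent=r["parent"], site=r["site"], year=int(r["year"]),
            pc=None if pd.isna(r["pc"]) or r["pc"] == "" else int(r["pc"]),
            group=r["group"], peak_cM=r["peak_cM"], lod=r["LOD"],
            ppve_pct=r["PPVE_pct"], effect=r["effect"],
            ci1=(r["ci1_lo"], r["ci1_hi"]), ci2=(r["ci2_lo"], r["ci2_hi"]),
            qtl_class=r["class"]))
    return recs


def main() -> None:
    out = cfg.OUT
    composite = io_mod.read_map(out / "map_composite.tsv", kind="composite")
    table = pd.read_csv(out / "qtl_records.tsv", sep="\t")
    projected, unprojected = [], 0
    for pop in sorted(cfg.POPULATIONS):
        for parent in (MATERNAL, PATERNAL):
            mspec = io_mod.read_map(out / f"map_{pop}_{parent}.tsv")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                frames = project.build_anchor_frames(mspec, composite)
            sub = table[(table["population"] == pop) & (table["parent"] == parent)]
            got, failed = project.project_records(_to_records(sub), frames)
            projected.extend(got)
            unprojected += len(failed)
    significant = [r for r in projected if r["qtl_class"] == scan.SIGNIFICANT]
    suggestive = [r for r in projected if r["qtl_class"] == scan.SUGGESTIVE]
    candidates = [r for r in projected if r["qtl_class"] == scan.INDICATIVE]
    retained = scan.retain_indicative(candidates, significant)
    final = significant + suggestive + retained
    print(f"projected {len(projected)} QTLs ({unprojected} unprojectable); "
          f"{len(significant)} significant, {len(suggestive)} suggestive, "
          f"{len(retained)}/{len(candidates)} indicative retained")

    clusters_by_trait = {}
    for trait in sorted({r["trait"] for r in final}):
        sub = [r for r in final if r["trait"] == trait]
        clusters_by_trait[trait] = project.consolidate_clusters(sub, composite)
    io_mod.write_table(project.clusters_to_frame(clusters_by_trait),
                       out / "qtl_clusters.tsv")
    stability = project.stability_table(clusters_by_trait)
    io_mod.write_table(stability, out / "stability.tsv")

    final_frame = pd.DataFrame(final)
    final_frame[["ci1_lo", "ci1_hi"]] = pd.DataFrame(final_frame.pop("ci1").tolist())
    final_frame[["ci2_lo", "ci2_hi"]] = pd.DataFrame(final_frame.pop("ci2").tolist())
    io_mod.write_table(final_frame, out / "qtl_projected.tsv")
    print(stability.to_string(index=False))


if __name__ == "__main__":
    main()
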