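"""Assemble parental, sub-composite and composite linkage maps.

Distorted markers are removed (chi-square 1:1 at alpha = 0.01), grouping
uses LOD >= 6.0 and theta <= 0.35, ordering minimises the sum of adjacent
recombination fractions, and maps are merged through shared anchors.
Prints Table-3-style summaries and within-cross colinearity.
"""

import importlib
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
cfg = importlib.import_module("00_config")

import budqtl.io as io_mod
from budqtl import report
from budqtl.linkage import MATERNAL, PATERNAL, build_parental_map, colinearity_stats, merge_maps


def main() -> None:
    out = cfg.OUT
    species = pd.read_csv(out / "species_map_truth.tsv", sep="\t")
    seg = dict(zip(species["marker"], species["seg_class"]))
    sub_composites = []
    for pop in sorted(cfg.POPULATIONS):
        maps = {}
        for parent in (MATERNAL, PATERNAL):
            geno = io_mod.read_genotypes(out / f"genotypes_{pop}_{parent}.tsv")
            spec, rep = build_parental_map(geno, f"{pop}_{parent}", seg_classes=seg)
            maps[parent] = spec
            io_mod.write_map(spec, out / f"map_{pop}_{parent}.tsv")
            s = report.map_summary(spec, unlinked=len(rep["unlinked"]),
                                   distorted=len(rep["distorted"]))
            print(f"map {spec.map_id}: {s.positioned}/{rep['available']} markers "
                  f"positioned on {s.n_groups} groups, {s.length_cM} cM "
                  f"({s.density_cM_per_marker} cM/marker), "
                  f"{s.distorted} distorted, {s.unlinked} unlinked")
        col = colinearity_stats(maps[MATERNAL], maps[PATERNAL])
        print(f"  colinearity {pop} maternal vs paternal: "
              f"{col['same_order']}/{col['shared']} ({col['percent']}%)")
        sub, _ = merge_maps([maps[MATERNAL], maps[PATERNAL]],
                            map_id=f"subcomposite_{pop}", kind="sub-composite")
        io_mod.write_map(sub, out / f"map_subcomposite_{pop}.tsv")
        sub_composites.append(sub)
    composite, repc = merge_maps(sub_composites, map_id="composite", kind="composite")
    io_mod.write_map(composite, out / "map_composite.tsv")
    s = report.map_summary(composite)
    print(f"composite map: {s.positioned} markers, {s.n_groups} groups, "
          f"{s.length_cM} cM ({s.density_cM_per_marker} cM/marker); "
          f"{len(repc['warnings'])} anchor warnings")


if __name__ == "__main__":
    main()
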