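"""Simulate the two clonally replicated full-sib families.

Draws one species map, plants a QTL architecture spanning the realistic
PPVE ranges (3-16% bud flush, 3-22% bud set, 2.5-10.5% height), and
simulates both crosses with their own marker subsets, genotyping error-free
but with ~0.5% missing calls.  Writes genotype, phenology, height and truth
files under results/analysis/.
"""

import importlib.util
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
cfg = importlib.import_module("00_config")

import budqtl.io as io_mod
from budqtl import simulate as sim
from budqtl.pipeline import _child_seeds, _subset_markers

def main() -> None:
    out = cfg.OUT
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(cfg.SEED, 16)
    map_cfg = sim.TrueMapConfig(
        n_groups=cfg.MAP["n_groups"],
        group_lengths=(cfg.MAP["group_length"],) * cfg.MAP["n_groups"],
        markers_per_group=cfg.MAP["markers_per_group"],
        class_mix=tuple(cfg.MAP["class_mix"]), seed=seeds[0])
    species_map = sim.simulate_parents_and_map(map_cfg)
    species_map.to_csv(out / "species_map_truth.tsv", sep="\t", index=False)

    design0 = sim.TrialDesign(n_progeny=2)
    qtls = sim.default_planted_qtls(species_map, design0, np.random.default_rng(seeds[1]))
    print(f"species map: {species_map['group'].nunique()} groups, "
          f"{len(species_map)} markers; planted {len(qtls)} QTLs")

    for i, (pop, pc) in enumerate(sorted(cfg.POPULATIONS.items())):
        design = sim.TrialDesign(n_progeny=pc["n_progeny"],
                                 years=tuple(pc["years"]))
        cross_map = _subset_markers(species_map, cfg.MARKER_KEEP_FRAC, seeds[2 + i])
        cross = sim.simulate_cross(pop, None, design, seeds[6 + i], qtls=qtls,
                                   true_map=cross_map)
        io_mod.write_genotypes(cross.genotypes.maternal, out / f"genotypes_{pop}_maternal.tsv")
        io_mod.write_genotypes(cross.genotypes.paternal, out / f"genotypes_{pop}_paternal.tsv")
        io_mod.write_phenology(cross.phenology, out / f"phenology_{pop}.tsv")
        io_mod.write_heights(cross.heights, out / f"heights_{pop}.tsv")
        io_mod.write_truth(cross.truth, out / f"truth_{pop}.json")
        print(f"cross {pop}: {pc['n_progeny']} progeny x 6 ramets, "
              f"{cross.genotypes.maternal.shape[1]} maternal / "
              f"{cross.genotypes.paternal.shape[1]} paternal markers, "
              f"years {pc['years']}")


if __name__ == "__main__":
    main()
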