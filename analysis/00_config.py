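"""Shared configuration for the numbered analysis drivers.

A desk-scale rendition of the two-family study design: two unrelated
crosses segregating for subsets of one 6-group species map, clonally
replicated progeny phenotyped for bud flush, bud set and height over two
years in outdoor (VES) and controlled indoor (AAFC) blocks.  Sizes are
chosen so the whole analysis chain runs in a few minutes on one CPU.
"""

from pathlib import Path

SEED = 20110310
OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"

MAP = {"n_groups": 12, "group_length": 120.0, "markers_per_group": 18,
       "class_mix": [0.32, 0.32, 0.36]}
POPULATIONS = {
    "P": {"n_progeny": 150, "years": [2004, 2005]},
    "D": {"n_progeny": 250, "years": [2006, 2007]},
}
MARKER_KEEP_FRAC = 0.85
N_PERM = 500          # permutations per threshold (reporting runs use >= 1,000)
SCAN_STEP = 1.0
COLOC_N = 1000
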