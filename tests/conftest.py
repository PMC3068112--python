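import numpy as np
import pandas as pd
import pytest

from budqtl import simulate as sim


def single_parent_map(positions, group="I", prefix="f", seg_class="maternal"):
    """Hand-built single-parent true-map table at given cM positions."""
    positions = np.asarray(positions, dtype=float)
    return pd.DataFrame({
        "group": group,
        "marker": [f"{prefix}01_{i:03d}" for i in range(len(positions))],
        "position_cM": positions,
        "seg_class": seg_class,
        "phase": 0,
    })


@pytest.fixture(scope="session")
def dense_map():
    """Evenly spaced maternal testcross map, 5 cM spacing over 60 cM."""
    return single_parent_map(np.arange(0.0, 61.0, 5.0))


@pytest.fixture(scope="session")
def small_true_map():
    cfg = sim.TrueMapConfig(n_groups=3, group_lengths=(100.0,) * 3,
                            markers_per_group=14, seed=2)
    return sim.simulate_parents_and_map(cfg)


@pytest.fixture(scope="session")
def small_cross(small_true_map):
    """One simulated family with a planted height QTL of 10% PPVE."""
    design = sim.TrialDesign(n_progeny=300, years=(2004,))
    sub = small_true_map[(small_true_map["group"] == "II")
                         & (small_true_map["seg_class"] == "maternal")]
    qtl = sim.PlantedQtl("height", "II", float(sub["position_cM"].iloc[1]),
                         "maternal", sim.effect_for_ppve(10.0, design, "height"))
    return sim.simulate_cross("T", None, design, 5, qtls=[qtl],
                              true_map=small_true_map), qtl
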