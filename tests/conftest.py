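import logging

import pandas as pd
import pytest

from hifscreen import ScreenDataset, SimulationConfig, simulate_screen
from hifscreen.simulate import reagent_table

logging.disable(logging.INFO)


@pytest.fixture()
def toy_plate() -> pd.DataFrame:
    """One 4-well plate: two samples, one control of each role."""
    return pd.DataFrame({
        "plate_id": ["p1"] * 4,
        "row": ["A", "A", "B", "B"],
        "col": [1, 2, 1, 2],
        "reagent_id": ["amp1", "amp2", "gfp", "sima"],
        "role": ["sample", "sample", "negative_control", "positive_control"],
        "firefly": [100.0, 900.0, 1000.0, 120.0],
        "renilla": [100.0, 100.0, 100.0, 100.0],
    })


@pytest.fixture()
def dual_sim():
    """Deterministic dual-reporter duplicate screen with planted effects."""
    cfg = SimulationConfig(
        n_genes=120, fraction_true_hits=0.1, fraction_viability=0.05,
        hit_effect=0.9, noise_cv=0.1, plate_effect_sd=0.15,
        with_renilla=True, n_replicates=2, seed=11,
    )
    ds, truth = simulate_screen(cfg)
    return cfg, ds, truth, reagent_table(cfg)


@pytest.fixture()
def noiseless_sim():
    """Noise-free dual-reporter screen: every stage is exact on it."""
    cfg = SimulationConfig(
        n_genes=40, fraction_true_hits=0.1, fraction_viability=0.1,
        hit_effect=0.8, noise_cv=0.0, plate_effect_sd=0.3,
        with_renilla=True, n_replicates=2, seed=4,
    )
    ds, truth = simulate_screen(cfg)
    return cfg, ds, truth, reagent_table(cfg)
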