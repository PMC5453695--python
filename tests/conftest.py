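import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def exp_records():
    """Six hand-made experimental records over three studies."""
    return pd.DataFrame({
        "study_id": ["S1", "S1", "S2", "S2", "S3", "S3"],
        "record_id": ["r1", "r2", "r1", "r2", "r1", "r2"],
        "treatment": ["water_addition"] * 2 + ["drought"] * 2 + ["warming"] * 2,
        "variable": ["N", "P", "N", "C", "N", "P"],
        "x_e": [0.95, 0.45, 1.15, 11.0, 1.06, 0.52],
        "s_e": [0.20, 0.10, 0.25, 2.2, 0.22, 0.11],
        "n_e": [5, 5, 8, 8, 6, 6],
        "x_c": [1.00, 0.50, 1.00, 10.0, 1.00, 0.50],
        "s_c": [0.21, 0.10, 0.24, 2.0, 0.20, 0.10],
        "n_c": [5, 5, 8, 8, 6, 6],
        "mat": [8.0, 8.0, 15.0, 15.0, 2.0, 2.0],
        "map": [450.0, 450.0, 900.0, 900.0, 300.0, 300.0],
        "ecosystem": ["grassland"] * 2 + ["forest"] * 2 + ["tundra"] * 2,
        "soil": ["Cambisol"] * 2 + ["Luvisol"] * 2 + ["Cambisol"] * 2,
    })


@pytest.fixture
def obs_sites():
    """Five observational sites across two regions, one variable."""
    return pd.DataFrame({
        "study_id": ["G1"] * 3 + ["G2"] * 2,
        "region": ["R1"] * 3 + ["R2"] * 2,
        "site_id": ["p1", "p2", "p3", "p1", "p2"],
        "variable": ["N"] * 5,
        "value": [0.8, 1.0, 1.3, 0.9, 1.1],
        "mat": [5.0, 7.0, 9.0, 4.0, 6.0],
        "map": [200.0, 450.0, 800.0, 300.0, 600.0],
        "mae": [1000.0, 1000.0, 1200.0, 900.0, 1100.0],
        "ecosystem": ["grassland"] * 3 + ["forest"] * 2,
        "soil": ["Cambisol"] * 3 + ["Luvisol"] * 2,
    })


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
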