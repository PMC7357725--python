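import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def tiny_trials() -> pd.DataFrame:
    """Three complete, valid observations in canonical units."""
    return pd.DataFrame({
        "study_id": ["S1", "S1", "S2"],
        "site_id": ["S1a", "S1b", "S2a"],
        "region": ["kenya", "kenya", "ssa_other"],
        "yield_t_mean": [3000.0, 2500.0, 1800.0],
        "yield_c_mean": [1500.0, 2000.0, 900.0],
        "yield_t_sd": [300.0, 250.0, 200.0],
        "yield_c_sd": [150.0, 260.0, 120.0],
        "n_t": [3.0, 3.0, 4.0],
        "n_c": [3.0, 3.0, 4.0],
        "n_rate": [60.0, 90.0, 30.0],
        "soil_ph": [5.1, 5.6, 6.0],
        "total_c": [12.0, 18.0, 8.0],
        "p_olsen": [6.0, np.nan, np.nan],
        "p_bray1": [np.nan, 50.0, np.nan],
        "p_bray2": [np.nan, np.nan, 10.0],
        "exch_k": [0.4, 0.8, 0.3],
        "clay": [20.0, 35.0, 15.0],
        "sand": [55.0, 40.0, 70.0],
        "silt": [25.0, 25.0, 15.0],
        "rainfall": [800.0, 950.0, 600.0],
        "altitude": [1500.0, 1600.0, 700.0],
        "soil_order": ["Nitisols", "Ferralsols", "Acrisols"],
        "texture_class": ["sandy loam", "clay loam", "sandy loam"],
        "aez": ["upper_midlands", "upper_midlands", "sub_humid"],
        "nutrient_type": ["N_only", "NPK", "N_only"],
        "manager": ["farmer", "farmer", "researcher"],
    })


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180915)
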