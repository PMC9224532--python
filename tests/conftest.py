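import numpy as np
import pandas as pd
import pytest

from csdskit.synthetic import GroupDesign, default_effects


@pytest.fixture
def design():
    return GroupDesign(n_per_group=4)


@pytest.fixture
def effects():
    return default_effects()


@pytest.fixture
def rng():
    return np.random.default_rng(20220614)


@pytest.fixture
def tiny_cohort():
    """Hand-built four-animal behavior table with known extremes.

    Animal a1 sits at the cohort minimum of every score parameter and
    a4 at the maximum; a2/a3 are interior.
    """
    return pd.DataFrame({
        "animal_id": ["a1", "a2", "a3", "a4"],
        "diet": ["control"] * 4,
        "stress": ["csds", "csds", "none", "none"],
        "of_time_center_s": [10.0, 40.0, 60.0, 100.0],
        "of_time_periphery_s": [500.0, 480.0, 450.0, 400.0],
        "of_distance_cm": [2000.0, 2100.0, 2500.0, 2600.0],
        "ld_time_light_s": [50.0, 100.0, 150.0, 200.0],
        "ld_time_dark_s": [400.0, 350.0, 300.0, 250.0],
        "ld_entries_light": [5, 8, 12, 15],
        "epm_time_open_s": [20.0, 40.0, 60.0, 90.0],
        "epm_time_center_s": [30.0, 40.0, 45.0, 50.0],
        "epm_distance_cm": [800.0, 900.0, 1000.0, 1100.0],
        "epm_entries_open": [3, 5, 8, 10],
        "epm_head_dips": [4, 7, 11, 14],
    })
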