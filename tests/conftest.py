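import numpy as np
import pandas as pd
import pytest

from epiage.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: 25/25 samples, 3000 probes, all effect classes planted."""
    return SimulationConfig(
        n_survived=25,
        n_deceased=25,
        n_probes=3000,
        n_dmp=30,
        n_dvp=30,
        n_dmr_regions=3,
        dmr_probes_per_region=5,
        bimodal_fraction=0.01,
        clock_n_cpgs=30,
        n_cell_probes=120,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_phenotype():
    """Hand-built 10-sample phenotype sheet (6 survived / 4 deceased)."""
    n = 10
    groups = ["survived"] * 6 + ["deceased"] * 4
    return pd.DataFrame(
        {
            "group": groups,
            "age": [60, 62, 64, 66, 68, 70, 61, 63, 65, 67],
            "sex": ["M", "F"] * 5,
            "complications": [0, 1, 0, 1, 0, 1, 0, 1, 0, 1],
            "followup_time": [16.8] * 6 + [5.0, 8.0, 11.0, 14.0],
            "event": [0] * 6 + [1] * 4,
        },
        index=pd.Index([f"S{i:03d}" for i in range(n)], name="sample_id"),
    )
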