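import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ccmlnc import synthetic_data as sim
from ccmlnc.io import CountMatrix

settings.register_profile(
    "ccmlnc",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ccmlnc")


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by read-only tests: 2 hubs, 30 partners."""
    cfg = sim.SimConfig(
        n_lncRNA=40,
        n_PCG=300,
        n_hubs=2,
        partners_per_hub=30,
        de_fraction_lnc=0.3,
        de_fraction_pcg=0.3,
        rng_seed=11,
    )
    cm, genes, truth = sim.simulate_dataset(cfg)
    return cfg, cm, genes, truth


@pytest.fixture()
def toy_counts():
    """Deterministic 5x4 integer matrix with labelled groups."""
    rng = np.random.default_rng(3)
    data = pd.DataFrame(
        rng.integers(1, 500, size=(5, 4)),
        index=[f"G{i}" for i in range(5)],
        columns=["s1", "s2", "s3", "s4"],
    )
    groups = {"s1": "case", "s2": "case", "s3": "control", "s4": "control"}
    return CountMatrix(data, groups)
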