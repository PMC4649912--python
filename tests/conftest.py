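import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import mirconcord as mc

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_table(rows):
    """Build a CtTable from (platform, run, sample, mirna, replicate, ct) tuples."""
    df = pd.DataFrame(
        rows, columns=["platform", "run", "sample", "mirna", "replicate", "ct"]
    )
    return mc.CtTable(df)


@pytest.fixture
def toy_table():
    """Two platforms, one run, duplicate replicates, one dropout."""
    rows = [
        ("P1", "run1", "s1", "miR-a", 1, 20.0),
        ("P1", "run1", "s1", "miR-a", 2, 20.2),
        ("P1", "run1", "s1", "miR-b", 1, 25.0),
        ("P1", "run1", "s1", "miR-b", 2, 25.0),
        ("P2", "run1", "s1", "miR-a", 1, 15.0),
        ("P2", "run1", "s1", "miR-a", 2, np.nan),
        ("P2", "run1", "s1", "miR-b", 1, 31.0),
        ("P2", "run1", "s1", "miR-b", 2, 33.5),
    ]
    return make_table(rows)


@pytest.fixture(scope="session")
def sim_table():
    """Small but complete simulated four-platform study."""
    cfg = mc.default_config(seed=7)
    table, ledger = mc.simulate_study(cfg)
    return table


@pytest.fixture(scope="session")
def sim_config():
    return mc.default_config(seed=7)
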