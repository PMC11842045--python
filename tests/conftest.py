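import numpy as np
import pandas as pd
import pytest

import ipd

MASTER_SEED = 2026


@pytest.fixture
def rng():
    return np.random.default_rng(MASTER_SEED)


@pytest.fixture
def small_stacked():
    """Tiny hand-written stacked table: 3 labeled, 2 unlabeled rows."""
    return pd.DataFrame({
        "Y": [1.0, 2.0, 3.0, np.nan, np.nan],
        "f": [1.1, 1.9, 3.2, 2.5, 0.5],
        "X1": [0.5, -0.2, 1.0, 0.3, -1.1],
        "X2": [1.0, 0.0, -0.5, 0.2, 0.8],
        "set_label": ["labeled", "labeled", "labeled", "unlabeled", "unlabeled"],
    })


@pytest.fixture(scope="session")
def sim_table():
    """One seeded draw of the full simulation pipeline (with predictions)."""
    return ipd.generate_stacked(ipd.SimConfig(seed=MASTER_SEED))


@pytest.fixture(scope="session")
def sim_dataset(sim_table):
    fml = ipd.parse_formula("Y - f ~ X1 + X2 + X3 + X4")
    return ipd.assemble(sim_table, fml, label="set_label"), fml


@pytest.fixture(scope="session")
def benchmark500():
    """The replicated linear-regression study shared by the acceptance
    checks: 500 seeded replicates of the 100/100/1000 design."""
    return ipd.run_benchmark(500, ipd.SimConfig(seed=MASTER_SEED), n_boot=100)
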