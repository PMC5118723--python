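import numpy as np
import pandas as pd
import pytest

from polyploid_eld import simdata
from polyploid_eld.tables_io import ExpressionTable


@pytest.fixture(scope="session")
def small_config() -> simdata.SimulationConfig:
    # small but statistically usable fixture: one-million-read libraries keep
    # Fisher supports small so the whole suite stays fast
    return simdata.SimulationConfig(
        n_genes=800,
        n_mirnas=60,
        library_sizes=(1_000_000, 1_000_000, 1_000_000),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_exp(small_config) -> simdata.SyntheticExperiment:
    return simdata.simulate_counts(small_config)


@pytest.fixture()
def tiny_table() -> ExpressionTable:
    counts = pd.DataFrame(
        {"A": [10, 0, 5, 100], "B": [20, 0, 5, 50], "C": [15, 0, 5, 400]},
        index=pd.Index(["g1", "g2", "g3", "g4"], name="feature_id"),
        dtype=np.int64,
    )
    return ExpressionTable(
        counts,
        library_sizes=pd.Series({"A": 10**6, "B": 10**6, "C": 10**6}),
        lengths=pd.Series({"g1": 1000, "g2": 500, "g3": 2000, "g4": 1000}),
    )
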