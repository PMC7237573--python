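import numpy as np
import pandas as pd
import pytest

from ienet import AbundanceTable, SampleDesign, study_scenario


@pytest.fixture(scope="session")
def scenario():
    """One deterministic study-scale cohort: 3 groups x 5 samples, 50 taxa."""
    return study_scenario(seed=7)


@pytest.fixture()
def toy_table():
    """4 taxa x 6 samples, closed, with hand-picked values."""
    rng = np.random.default_rng(42)
    raw = rng.uniform(0.1, 2.0, size=(4, 6))
    data = pd.DataFrame(
        raw / raw.sum(axis=0),
        index=["taxA", "taxB", "taxC", "taxD"],
        columns=[f"s{i}" for i in range(6)],
    )
    return AbundanceTable(data, rank="genus", closed=True)


@pytest.fixture()
def two_group_design():
    groups = pd.Series(
        {"s0": "H", "s1": "H", "s2": "H", "s3": "D", "s4": "D", "s5": "D"}
    )
    return SampleDesign(groups, reference="H")
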