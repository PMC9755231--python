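import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import microtpl as m

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_table(values, otu_ids=None, sample_ids=None) -> m.OtuTable:
    """OtuTable from a nested list / array (rows = OTUs, cols = samples)."""
    arr = np.asarray(values, dtype=float)
    otus = otu_ids or [f"OTU_{i + 1}" for i in range(arr.shape[0])]
    samples = sample_ids or [f"S{i + 1}" for i in range(arr.shape[1])]
    return m.OtuTable(pd.DataFrame(arr, index=otus, columns=samples))


@pytest.fixture
def tiny_table() -> m.OtuTable:
    # 3 OTUs x 2 samples, total abundance 14
    return make_table([[1, 2], [0, 5], [3, 3]])


@pytest.fixture
def tiny_metadata() -> list:
    return [
        m.SampleMetadata("S1", "F_sp", "A", m.Morphometrics(12.0, 10.0, 40.0)),
        m.SampleMetadata("S2", "F_sp", "B", m.Morphometrics(13.0, 11.0, 42.0)),
    ]


@pytest.fixture
def small_study():
    """3 host species, 30 samples, aggregated Type-III law (b = 1.8)."""
    spec = m.default_study_spec(
        seed=42, n_species=3, total_samples=30, otus_per_species=60,
        n_shared_otus=30, n_sites=4,
    )
    table, meta, taxonomy = m.simulate_study(spec)
    return m.join_tables(table, meta), taxonomy
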