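import numpy as np
import pytest

from somatoref.cohort import (
    CohortConfig,
    generate_cohort,
    generate_discharge,
    records_to_frame,
)
from somatoref.pooling import build_reference_table, load_reference_studies


@pytest.fixture(scope="session")
def pooled_refs():
    """Pooled healthy references computed from the packaged study table."""
    return build_reference_table(load_reference_studies())


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (79 records, 45 with discharge)."""
    cc = CohortConfig()
    records = generate_cohort(cc, seed=7)
    return generate_discharge(records, cc, seed=7)


@pytest.fixture(scope="session")
def cohort_frame(default_cohort):
    return records_to_frame(default_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
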