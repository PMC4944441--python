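import numpy as np
import pandas as pd
import pytest

from dysbiome.containers import CohortMetadata, TaxonTable
from dysbiome.synth import CohortSimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated default cohort shared across read-only tests."""
    return simulate_cohort(CohortSimConfig(seed=20240901))


@pytest.fixture()
def toy_table():
    data = pd.DataFrame(
        [[10.0, 5.0, 0.0], [2.0, 8.0, 4.0]],
        index=["s1", "s2"],
        columns=[
            "k__Bacteria;p__A;c__B;o__C;f__D;g__E",
            "k__Bacteria;p__A;c__B;o__C;f__D;g__F",
            "k__Bacteria;p__A;c__B;o__C;f__G;g__",
        ],
    )
    return TaxonTable(data, value_kind="counts")


@pytest.fixture()
def toy_metadata():
    return CohortMetadata(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3"],
        "subject_id": ["p1", "p1", "c1"],
        "group": ["CD", "CD", "control_familial"],
        "responder": ["responder", "responder", "not_applicable"],
        "time_days": [0.0, 30.0, 0.0],
        "calprotectin": [500.0, 200.0, np.nan],
        "activity_index": [30.0, 10.0, np.nan],
        "pretreatment_flag": [True, False, False],
    }))
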