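import numpy as np
import pandas as pd
import pytest

from gutcompass import AbundanceTable, SampleMetadata


@pytest.fixture
def tiny_table():
    """Four samples, four species across two genera, percent rows."""
    labels = [
        "k__Bacteria|p__P1|c__C1|o__O1|f__F1|g__G1|s__G1_sp1",
        "k__Bacteria|p__P1|c__C1|o__O1|f__F1|g__G1|s__G1_sp2",
        "k__Bacteria|p__P1|c__C1|o__O1|f__F2|g__G2|s__G2_sp1",
        "k__Bacteria|p__P1|c__C1|o__O1|f__F2|g__G2|s__G2_sp2",
    ]
    data = pd.DataFrame(
        [[25.0, 25.0, 25.0, 25.0],
         [50.0, 25.0, 12.5, 12.5],
         [10.0, 20.0, 30.0, 40.0],
         [60.0, 40.0, 0.0, 0.0]],
        index=["s1", "s2", "s3", "s4"], columns=labels,
    )
    return AbundanceTable(data=data, rank="species")


@pytest.fixture
def tiny_metadata():
    df = pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "cohort": ["A", "A", "B", "B"],
        "age": [60.0, 65.0, 55.0, 70.0],
        "sex": [0, 1, 0, 1],
        "med_J01": [1, 0, 0, 1],
    })
    return SampleMetadata(data=df, medication_columns=["med_J01"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
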