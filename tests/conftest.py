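import numpy as np
import pandas as pd
import pytest

from mapsig import ExpressionMatrix, ProbeAnnotation


@pytest.fixture
def raw_matrix():
    """3 probes x 4 samples of positive intensities."""
    data = pd.DataFrame(
        [[100.0, 200.0, 150.0, 120.0],
         [1000.0, 900.0, 1100.0, 950.0],
         [50.0, 55.0, 45.0, 60.0]],
        index=["p1", "p2", "p3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(data, "raw")


@pytest.fixture
def annotation():
    return ProbeAnnotation({"p1": "GENEA", "p2": "GENEA", "p3": "GENEB"})


def make_normalized(values, feature_ids=None, sample_ids=None):
    values = np.asarray(values, float)
    feature_ids = feature_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=feature_ids, columns=sample_ids), "normalized"
    )
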