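import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from emtdubscreen import ClinicalTable, ExpressionMatrix, GeneSet

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def toy_matrix():
    """3-gene x 3-sample matrix used by the worked EMT-metric example."""
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]],
        index=["CDH1", "G1", "G2"],
        columns=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(data, cohort="TOY")


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.normal(size=(4, 12)),
        index=["VIM", "CDH1", "DUB1", "DUB2"],
        columns=[f"s{i}" for i in range(12)],
    )
    return ExpressionMatrix(data, cohort="SMALL")


@pytest.fixture
def clinical_four():
    """Events at 1 and 3, censoring at 2 and 4 (hand-computable KM curve)."""
    return ClinicalTable(pd.DataFrame({
        "sample_id": ["a", "b", "c", "d"],
        "time": [1.0, 2.0, 3.0, 4.0],
        "event": [1, 0, 1, 0],
    }))


def make_clinical(times, events, prefix="p"):
    return ClinicalTable(pd.DataFrame({
        "sample_id": [f"{prefix}{i}" for i in range(len(times))],
        "time": list(map(float, times)),
        "event": list(map(int, events)),
    }))


@pytest.fixture
def dub_family():
    return GeneSet(name="dubs", symbols=("DUB1", "DUB2"))
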