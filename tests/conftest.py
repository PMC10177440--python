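import numpy as np
import pandas as pd
import pytest

from umstrat import Cohort, default_config, generate_cohort
from umstrat.cohort import COLUMNS


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """One default-configuration cohort shared across tests."""
    return generate_cohort(default_config(seed=7))


@pytest.fixture()
def tiny_cohort() -> Cohort:
    """Hand-built 6-record cohort covering both subgroups and all decisions."""
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(6)],
            "age": [55, 60, 70, 45, 62, 58],
            "sex": ["F", "M", "M", "F", "M", "F"],
            "diameter_mm": [10.0, 12.0, 15.0, 8.0, 11.0, 13.0],
            "height_mm": [3.0, 4.0, 6.0, 2.5, 3.5, 5.0],
            "ciliary_body": [0, 0, 1, 0, 0, 0],
            "extraocular": [0, 0, 0, 0, 1, 0],
            "chr3_status": ["monosomy", "disomy", "monosomy", "unknown", "unknown", "disomy"],
            "mam5_full": [0.30, 0.04, 0.60, 0.05, 0.02, 0.10],
            "mam5_nochr3": [0.20, 0.06, 0.40, 0.05, 0.02, 0.12],
            "mam5_nogenetics": [0.25, 0.05, 0.50, 0.06, 0.03, 0.11],
            "stage": ["IIB", "I", "IIIC", "IIA", "I", "IIA"],
            "endpoint": [1, 0, 1, 0, 0, 0],
        },
        columns=list(COLUMNS),
    )
    return Cohort(df)


def brute_force_auc(scores: np.ndarray, endpoints: np.ndarray) -> float:
    """O(m*n) pair-counting AUC with half credit for ties."""
    pos = np.asarray(scores, float)[np.asarray(endpoints, bool)]
    neg = np.asarray(scores, float)[~np.asarray(endpoints, bool)]
    total = 0.0
    for x in pos:
        total += np.sum(x > neg) + 0.5 * np.sum(x == neg)
    return total / (len(pos) * len(neg))
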