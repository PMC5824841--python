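import numpy as np
import pandas as pd
import pytest

from elasto_bcp import COHORT_COLUMNS, CohortDataset


def make_cohort(benign_scores, malignant_scores, **overrides) -> CohortDataset:
    """Build a minimal valid cohort from two lists of BCP percents."""
    n_b, n_m = len(benign_scores), len(malignant_scores)
    labels = ["benign"] * n_b + ["malignant"] * n_m
    scores = list(benign_scores) + list(malignant_scores)
    n = n_b + n_m
    df = pd.DataFrame(
        {
            "node_id": [f"LN{i:03d}" for i in range(n)],
            "station": ["7"] * n,
            "pathology_subtype": ["unspecified"] * n,
            "label": labels,
            "bcp_percent": [float(s) for s in scores],
            "short_axis_mm": [12.0] * n,
            "round_shape": [0] * n,
            "distinct_margin": [0] * n,
            "heterogeneous_echo": [0] * n,
            "vascular_pattern": [0] * n,
            "suv_gt_2_5": [np.nan] * n,
        },
        columns=list(COHORT_COLUMNS),
    )
    for col, values in overrides.items():
        df[col] = values
    return CohortDataset(records=df)


@pytest.fixture
def cohort_factory():
    return make_cohort


@pytest.fixture
def small_cohort():
    # benign 10, 35; malignant 30, 80 -> 3 concordant of 4 pairs
    return make_cohort([10.0, 35.0], [30.0, 80.0])
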