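import numpy as np
import pandas as pd
import pytest

from mirmark.datatypes import CohortMatrix


def build_cohort(values, n_tumour, n_normal, cohort_id="C1", mirnas=None):
    """CohortMatrix from a 2-D array whose first n_tumour columns are tumour."""
    values = np.asarray(values, float)
    n_feat, n_samples = values.shape
    assert n_samples == n_tumour + n_normal
    samples = [f"{cohort_id}-T{i}" for i in range(n_tumour)] + [
        f"{cohort_id}-N{i}" for i in range(n_normal)
    ]
    labels = pd.Series(["tumour"] * n_tumour + ["normal"] * n_normal, index=samples)
    idx = mirnas if mirnas is not None else [f"miR-{i + 1:03d}" for i in range(n_feat)]
    return CohortMatrix(cohort_id, pd.DataFrame(values, index=idx, columns=samples), labels)


@pytest.fixture
def make_cohort():
    return build_cohort


@pytest.fixture
def tiny_cohort():
    """3 miRNAs x 4 samples (2 tumour, 2 normal), one missing entry."""
    values = np.array(
        [
            [5.0, 6.0, 8.0, 9.0],
            [7.0, np.nan, 7.5, 7.2],
            [3.0, 3.1, 2.9, 3.2],
        ]
    )
    return build_cohort(values, 2, 2)
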