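import numpy as np
import pandas as pd
import pytest

from kdsig.core import ExpressionMatrix
from kdsig.synth import CohortConfig, generate_cohort


def matrix_from(values, sample_ids=None, transcript_ids=None, scale="log2"):
    """Build an ExpressionMatrix from a samples x transcripts array."""
    values = np.asarray(values, dtype=float)
    n_s, n_t = values.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(n_s)]
    transcript_ids = transcript_ids or [f"T{j}" for j in range(n_t)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=sample_ids, columns=transcript_ids), scale=scale
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort shared by read-only tests."""
    cfg = CohortConfig(
        n_transcripts=1500,
        n_modules=14,
        module_size_range=(10, 25),
        n_per_group={
            "cKD_training": 20,
            "HC_training": 12,
            "cKD_test": 15,
            "HC_test": 8,
            "inKD_validation": 8,
            "HC_validation": 5,
            "AdV": 12,
            "GAS": 8,
            "HC_febrile": 6,
        },
        seed=42,
    )
    return generate_cohort(cfg)


def ids(annotations, group=None, cohort=None, timepoint="pre"):
    return [
        a.sample_id
        for a in annotations
        if (group is None or a.group == group)
        and (cohort is None or a.cohort == cohort)
        and a.timepoint == timepoint
    ]
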