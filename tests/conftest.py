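import numpy as np
import pandas as pd
import pytest

from captraj import CapConfig, assign_cap, design_response, generate_cohort
from captraj.validation import PROBE_TRUTH, probe_scenario


def probe_dataset(seed=0, cap_config=None, **kw):
    """Fit-ready dataset generated from :func:`probe_scenario`."""
    cohort = generate_cohort(probe_scenario(seed=seed, **kw))
    capped = assign_cap(cohort, cap_config or CapConfig())
    return design_response(capped, "probe")


@pytest.fixture
def tiny_cohort() -> pd.DataFrame:
    """Six hand-built scans (3 subjects, 2 studies, all groups)."""
    return pd.DataFrame(
        {
            "subject_id": ["a", "a", "b", "b", "c", "c"],
            "study": ["A", "A", "A", "A", "B", "B"],
            "group": ["control", "control", "premanifest", "premanifest", "manifest", "manifest"],
            "visit_index": [0, 1, 0, 1, 0, 1],
            "age": [30.0, 31.0, 40.0, 41.2, 55.0, 56.1],
            "cag": [np.nan, np.nan, 42.0, 42.0, 45.0, 45.0],
            "icv": [1.5e6] * 6,
            "whole_brain": [1.1e6, 1.1e6, 1.05e6, 1.04e6, 0.95e6, 0.94e6],
            "qc_pass": [True] * 6,
            "putamen": [8000.0, 7990.0, 7500.0, 7300.0, 5200.0, 5100.0],
            "caudate": [7400.0, 7380.0, 7000.0, 6900.0, 4900.0, 4850.0],
        }
    )
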