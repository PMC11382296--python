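import numpy as np
import pandas as pd
import pytest

from clckit.config import AnalysisConfig, CohortConfig


@pytest.fixture(scope="session")
def analysis():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast cohort used by several structural tests."""
    return CohortConfig(n_subjects=2, days=3, seed=11)


def make_records(sr_hr_pairs, start="2023-01-02 10:00"):
    """Minute records from (sr, hr) pairs, one per consecutive minute."""
    t0 = pd.Timestamp(start)
    return pd.DataFrame({
        "timestamp": [t0 + pd.Timedelta(minutes=i) for i in range(len(sr_hr_pairs))],
        "sr": [float(s) for s, _ in sr_hr_pairs],
        "hr": [float(h) for _, h in sr_hr_pairs],
    })


@pytest.fixture(scope="session")
def records_factory():
    return make_records
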