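import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from painnet import (
    AnalysisConfig,
    SyntheticSpec,
    default_registry,
    generate_cohort,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def default_cohort():
    """One default-spec synthetic cohort shared by read-only tests."""
    cohort, truth = generate_cohort(SyntheticSpec(rng_seed=7))
    return cohort, truth


@pytest.fixture()
def tiny_cohort_csv(tmp_path, registry):
    """Three-record long-format file with known cells."""
    path = tmp_path / "tiny.csv"
    pd.DataFrame({
        "subject_id": ["s1", "s1", "s2"],
        "group": ["KOA", "KOA", "HOA"],
        "visit": ["baseline", "m3", "baseline"],
        "measure_id": ["NRS", "NRS", "HADS-A"],
        "value": [6.5, 2.0, 11.0],
    }).to_csv(path, index=False)
    return path
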