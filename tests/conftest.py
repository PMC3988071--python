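import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_cases() -> pd.DataFrame:
    from hbmkit.cohort import load_study_cases

    return load_study_cases()


@pytest.fixture()
def tiny_effects() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rsid": ["rs1", "rs2", "rs3"],
            "effect_allele": ["A", "C", "G"],
            "other_allele": ["G", "T", "A"],
            "beta": [0.04, 0.05, 0.06],
            "maf": [0.3, 0.4, 0.2],
        }
    )


@pytest.fixture()
def tiny_genotypes() -> pd.DataFrame:
    return pd.DataFrame(
        [[2.0, 1.0, 0.0], [1.0, np.nan, 2.0], [0.0, 0.0, 1.0]],
        index=["A", "B", "C"],
        columns=["rs1", "rs2", "rs3"],
    )


@pytest.fixture()
def tiny_reference() -> pd.DataFrame:
    # rs2 reference dosages average to 1.0, so its mean score is 1.0 * 0.05.
    return pd.DataFrame(
        [[0.0, 0.0, 0.0], [1.0, 1.0, 1.0], [2.0, 2.0, 2.0], [1.0, 1.0, 0.0], [0.0, 1.0, 2.0]],
        index=[f"R{i}" for i in range(5)],
        columns=["rs1", "rs2", "rs3"],
    )
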