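import numpy as np
import pandas as pd
import pytest

import riskscores as rs


@pytest.fixture(scope="session")
def demo_cohort() -> rs.Dataset:
    """Small claims-like cohort shared by integration-style tests."""
    return rs.make_claims_like_cohort(seed=7, n=20_000)


@pytest.fixture()
def tiny_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "flag": [0, 1, 0, 1, 1, 0],
            "cost": [0.0, 12.5, 3.0, 250.0, 80.0, 0.0],
            "y": [0, 1, 0, 1, 0, 0],
        }
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
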