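import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def make_covariates(n, rng, site="colon"):
    """Small covariate frame with realistic category levels."""
    ids = [f"s{i:03d}" for i in range(n)]
    frame = pd.DataFrame({
        "age": rng.normal(65.0, 9.0, n).clip(30, 79),
        "sex": rng.choice(["male", "female"], n),
        "race": rng.choice(["white", "hispanic", "black"], n, p=[0.8, 0.1, 0.1]),
        "site": rng.choice(["colon", "rectal"], n) if site == "mixed" else site,
    }, index=pd.Index(ids, name="sample_id"))
    return frame


@pytest.fixture
def covariates60(rng):
    return make_covariates(60, rng)
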