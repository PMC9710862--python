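import numpy as np
import pandas as pd
import pytest

from cvdval import engines


@pytest.fixture(scope="session")
def score_coeffs():
    return engines.load_score_coefficients()


@pytest.fixture(scope="session")
def fnf_table():
    return engines.load_fnf_multipliers()


@pytest.fixture(scope="session")
def globo_lab():
    return engines.load_globorisk_coefficients("lab")


@pytest.fixture(scope="session")
def globo_office():
    return engines.load_globorisk_coefficients("office")


def random_profiles(rng, n, model="SCORE"):
    """Random valid profile frame for batch prediction."""
    age_hi = 70 if model in ("SCORE", "SCORE_FNF") else 74
    return pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "age": rng.uniform(40, age_hi, n),
            "sex": rng.choice(["male", "female"], n),
            "sbp": rng.uniform(100, 200, n),
            "ratio": rng.uniform(2, 9, n),
            "tc": rng.uniform(3, 9, n),
            "bmi": rng.uniform(18, 42, n),
            "smoker": rng.integers(0, 2, n).astype(float),
            "diabetes": rng.integers(0, 2, n).astype(float),
            "rheumatoid_arthritis": rng.random(n) < 0.1,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
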