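import numpy as np
import pandas as pd
import pytest

from etiohet.riskmetrics import RiskFactorTable


def make_risk_table(n, seed=0, constant=False):
    """Random risk-factor table with the standard covariate roles."""
    rng = np.random.default_rng(seed)
    if constant:
        df = pd.DataFrame({
            "smoking": ["never"] * n,
            "gender": ["male"] * n,
        }, index=[f"case{i}" for i in range(n)])
        return RiskFactorTable(df, {"smoking": ["never"], "gender": ["male"]})
    df = pd.DataFrame({
        "smoking": rng.choice(["never", "former", "current"], n),
        "bmi": rng.choice(["normal", "overweight", "obese"], n),
        "hypertension": rng.choice(["no", "yes"], n),
        "gender": rng.choice(["male", "female"], n),
        "age": rng.normal(60, 10, n),
    }, index=[f"case{i}" for i in range(n)])
    return RiskFactorTable(
        df,
        {
            "smoking": ["never", "former", "current"],
            "bmi": ["normal", "overweight", "obese"],
            "hypertension": ["no", "yes"],
            "gender": ["male", "female"],
        },
        ["age"],
    )


def random_rate_matrix(rng, n, m):
    """Random valid population rate matrix (positive, mixed scales)."""
    base = rng.lognormal(mean=-3.0, sigma=1.0, size=(n, 1))
    mix = rng.dirichlet(np.full(m, rng.uniform(0.5, 3.0)), size=n)
    return base * mix * rng.uniform(0.5, 2.0, size=(1, m))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
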