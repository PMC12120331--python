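import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_deployment():
    """A short synthetic deployment shared by QC/aggregation tests."""
    from hrtag import (
        DeploymentConfig,
        generate_covariates,
        generate_feeding_log,
        generate_hr_series,
        generate_logger_records,
    )

    config = DeploymentConfig(n_days=12, seed=11)
    cov = generate_covariates(config)
    hrm = generate_hr_series(cov, seed=11)
    records = generate_logger_records(cov, hrm, config)
    feeding = generate_feeding_log(cov)
    return config, cov, hrm, records, feeding


@pytest.fixture(scope="session")
def tiny_daily():
    """A 10-day daily table with known integer responses."""
    rng = np.random.default_rng(5)
    n = 10
    return pd.DataFrame(
        {
            "date": pd.date_range("2022-08-01", periods=n).date,
            "hrm": rng.poisson(50, n),
            "tpm": np.linspace(27, 20, n),
            "tpiq": np.linspace(0.3, 1.0, n),
            "acm": rng.uniform(25, 45, n),
            "tf": rng.uniform(0, 20, n).round(1),
            "n_records": 120,
        }
    )
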