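import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tractlat.fp import FPSpec
from tractlat.model import CentileChart, NormativeModel

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_constant_model(
    mu: float = 0.0, sigma: float = 1.0, sex_effect: float | None = None,
    age_range=(0.0, 100.0),
) -> NormativeModel:
    """Hand-built location-scale model with constant mu and sigma."""
    return NormativeModel(
        spec_mu=FPSpec(()),
        spec_sigma=FPSpec(()),
        age_offset=1.0,
        mu_intercept=mu,
        mu_fp=np.empty(0),
        mu_sex=sex_effect,
        mu_cohorts={},
        sigma_intercept=float(np.log(sigma)),
        sigma_fp=np.empty(0),
        sigma_sex=None,
        sigma_cohorts={},
        tau2_mu=None,
        tau2_sigma=None,
        n=100,
        k=2,
        loglik=0.0,
        bic=0.0,
        converged=True,
        n_iter=1,
        grad_norm=0.0,
        age_range=age_range,
        cohort_mode="none",
    )


def make_median_chart(age_grid, median, tract="AF", feature="FA") -> CentileChart:
    """Chart whose only level is the median curve (for analytics tests)."""
    median = np.asarray(median, dtype=float)
    return CentileChart(
        tract=tract,
        feature=feature,
        context="average",
        age_grid=np.asarray(age_grid, dtype=float),
        levels=(50.0,),
        values=median[:, None],
    )


@pytest.fixture()
def iid_table():
    """Single-cohort iid Gaussian LI table (for closed-form fitting checks)."""
    rng = np.random.default_rng(42)
    n = 400
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "age_years": rng.uniform(0.0, 100.0, n),
            "sex": "female",
            "cohort_id": "c0",
            "handedness": "right",
            "li": rng.normal(0.03, 0.05, n),
        }
    )
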