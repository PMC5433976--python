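"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import multivariate_normal

from redstart.bayes_model import ModelParams
from redstart.capture_data import CaptureRecord, table_from_records


def random_model_params(rng: np.random.Generator) -> ModelParams:
    """Random but physically plausible parameter set."""
    rho = rng.uniform(-0.8, 0.8, size=4)
    return ModelParams.from_sd_rho(
        w0=16 + rng.normal(0, 1, 4),
        w1=rng.normal(0, 0.05),
        w2=rng.normal(0, 0.02),
        p0=65 + rng.normal(0, 2, 4),
        p1=rng.normal(0, 0.05),
        p2=rng.normal(0, 0.02),
        sigma_weight=rng.uniform(0.5, 2.0, 4),
        sigma_primary=rng.uniform(0.8, 2.5, 4),
        rho=rho,
        s0=rng.normal(0, 1),
        s1=rng.normal(0, 0.1),
        s2=rng.normal(0, 0.05),
        a0=rng.normal(0, 1),
        a1=rng.normal(0, 0.1),
        a2=rng.normal(0, 0.05),
    )


def oracle_record_log_density(params, age, sex, weight, primary, day_c, year_c) -> float:
    """Textbook-formula density: scipy MVN pdf plus explicit Bernoulli masses."""
    g = sex + 2 * age
    mean = np.array(
        [
            params.w0[g] + params.w1 * day_c + params.w2 * year_c,
            params.p0[g] + params.p1 * day_c + params.p2 * year_c,
        ]
    )
    ll = multivariate_normal(mean=mean, cov=params.sigma[g]).logpdf([weight, primary])
    p_male = expit(params.s0 + params.s1 * day_c + params.s2 * year_c)
    p_adult = expit(params.a0 + params.a1 * day_c + params.a2 * year_c)
    ll += np.log(p_male if sex == 1 else 1 - p_male)
    ll += np.log(p_adult if age == 1 else 1 - p_adult)
    return float(ll)


def oracle_label_posterior(params, weight, primary, day_c, year_c, age, sex, paradoxus=False):
    """Brute-force enumeration of the admissible completions via the oracle density."""
    completions = []
    weights = []
    for a in (0, 1):
        for s in (0, 1):
            if age is not None and a != age:
                continue
            if sex is not None and s != sex:
                continue
            if paradoxus and not (a == 0 and s == 1):
                continue
            completions.append((a, s))
            weights.append(
                np.exp(oracle_record_log_density(params, a, s, weight, primary, day_c, year_c))
            )
    weights = np.asarray(weights)
    return completions, weights / weights.sum()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_table():
    """Six records over two years, one missing sex, one missing both labels."""
    records = [
        CaptureRecord("a1", 2000, 280, 0, 0, 15.2, 63.5, "female_colored"),
        CaptureRecord("a2", 2000, 282, 0, 1, 16.1, 67.2, "paradoxus"),
        CaptureRecord("a3", 2000, 285, 1, 1, 16.5, 68.1, None),
        CaptureRecord("b1", 2001, 281, 1, 0, 15.8, 64.0, "female_colored"),
        CaptureRecord("b2", 2001, 284, 0, None, 15.4, 63.8, "female_colored"),
        CaptureRecord("b3", 2001, 286, None, None, 16.2, 66.5, None),
    ]
    return table_from_records(records, season_midpoint_day=283, reference_year=2000)
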