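"""Shared fixtures: small synthetic cohorts and one reusable hierarchical fit.

Everything is generated programmatically from fixed seeds; the expensive
study-scale fit is session-scoped and shared by the power/recovery and
correlation tests.
"""

import warnings

import numpy as np
import pytest

from ambddm import (
    CohortConfig,
    ConditionKey,
    ModelSpec,
    build_model,
    filter_trials,
    fit,
    generate_cohort,
)
from ambddm.cohort import HIGH, LOW, MINIMAL, SHORT, SINGLE

TWO_CONDITIONS = tuple(ConditionKey(SHORT, c, MINIMAL, SINGLE) for c in (LOW, HIGH))


@pytest.fixture(autouse=True)
def _quiet_mcmc_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="MCMC diagnostics")
        yield


@pytest.fixture(scope="session")
def clean_cohort():
    """12 persons x 2 single-probe conditions, no missingness/contaminants."""
    cfg = CohortConfig(
        n_participants=12,
        conditions=TWO_CONDITIONS,
        session_missing_prob=0.0,
        contaminant_rate=0.0,
        censor_at_deadline=False,
        seed=101,
    )
    trials, truth = generate_cohort(cfg)
    return cfg, trials, truth


@pytest.fixture(scope="session")
def clean_retained(clean_cohort):
    _, trials, _ = clean_cohort
    retained, _ = filter_trials(trials, expected_per_participant=120)
    return retained


@pytest.fixture(scope="session")
def small_fit(clean_retained):
    """Short-chain fit of the clean cohort, shared across model/PPC tests."""
    spec = ModelSpec(chains=2, warmup=400, draws=400, seed=7)
    return fit(build_model(spec, clean_retained))


@pytest.fixture(scope="session")
def study_scale_fit():
    """68 persons x 2 conditions with the study-scale bias effect (+0.15 logit)
    and the study-scale age-drift correlation (-0.45); one fit reused by the
    contrast-power and correlation-recovery tests."""
    cfg = CohortConfig(
        n_participants=68,
        conditions=TWO_CONDITIONS,
        session_missing_prob=0.0,
        contaminant_rate=0.0,
        censor_at_deadline=False,
        seed=424,
    )
    trials, truth = generate_cohort(cfg)
    retained, _ = filter_trials(trials, expected_per_participant=120)
    spec = ModelSpec(chains=2, warmup=500, draws=500, seed=42)
    result = fit(build_model(spec, retained))
    return cfg, trials, truth, result


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
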