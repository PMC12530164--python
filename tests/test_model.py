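"""Hierarchical DDM: likelihood assembly, coding rule, sampler contracts,
posterior summaries and contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from ambddm import (
    CohortConfig,
    DDMParams,
    ModelSpec,
    build_model,
    condition_summaries,
    contrasts,
    filter_trials,
    fit,
    generate_cohort,
    wfpt_logdensity,
)
from ambddm.model import PARAM_NAMES, PosteriorSummary, _marginal_mean_draws, summarize_draws
from tests.conftest import TWO_CONDITIONS


def _trial_rows(rts_ms, truths, responses, version=2):
    return pd.DataFrame(
        {
            "participant_id": 1,
            "age": 50.0,
            "day": 1,
            "version_index": version,
            "study_time_ms": 500,
            "change_prob": "low_50",
            "deadline_ms": 10_000,
            "probe_type": "single_probe",
            "trial_index": np.arange(1, len(rts_ms) + 1),
            "truth": truths,
            "response": responses,
            "rt_ms": rts_ms,
        }
    )


def test_build_rejects_empty_and_nonpositive_rts():
    with pytest.raises(ValueError):
        build_model(ModelSpec(), pd.DataFrame())
    bad = _trial_rows([0.0], ["same"], ["same"])
    with pytest.raises(ValueError):
        build_model(ModelSpec(), bad)


def test_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(chains=1)
    with pytest.raises(ValueError):
        ModelSpec(draws=0)
    with pytest.raises(ValueError):
        ModelSpec(fixed_params={"nope": 1.0})


def test_stimulus_coding_negates_drift_on_same_trials():
    # one *same* trial answered "different": contributes the upper-boundary
    # density with the condition drift negated
    rt_s = 0.9
    df = _trial_rows([rt_s * 1000], ["same"], ["different"])
    model = build_model(ModelSpec(), df)
    theta = np.array([[1.2, 0.3, 0.5, 0.25]])
    expected = wfpt_logdensity(
        rt_s, "upper", DDMParams(-1.2, np.exp(0.5), expit(0.3), 0.25)
    )
    assert model.data_loglik(theta) == pytest.approx(expected, abs=1e-12)


def test_joint_log_density_matches_independent_sum():
    # ten trials over two persons in one condition; the model's joint density
    # must equal a hand-assembled sum of Wiener terms and normal log-priors
    rng = np.random.default_rng(5)
    rts = rng.uniform(500, 2500, 10)
    truths = np.where(rng.random(10) < 0.5, "different", "same")
    resps = np.where(rng.random(10) < 0.6, "different", "same")
    df = pd.concat(
        [
            _trial_rows(rts[:6], truths[:6], resps[:6]).assign(participant_id=1),
            _trial_rows(rts[6:], truths[6:], resps[6:]).assign(participant_id=2),
        ],
        ignore_index=True,
    )
    spec = ModelSpec()
    model = build_model(spec, df)
    theta = np.array([[1.0, 0.2, 0.6, 0.2], [0.8, -0.1, 0.5, 0.25]])
    mu = np.array([[0.9, 0.0, 0.55, 0.22]])
    sigma = np.array([[0.4, 0.3, 0.2, 0.1]])

    expected = 0.0
    for cell, pid in enumerate((1, 2)):
        sub = df[df.participant_id == pid]
        d, b_logit, a_log, ndt = theta[cell]
        params_up = DDMParams(d, np.exp(a_log), expit(b_logit), ndt)
        for _, row in sub.iterrows():
            drift = d if row.truth == "different" else -d
            choice = "upper" if row.response == "different" else "lower"
            expected += wfpt_logdensity(
                row.rt_ms / 1000.0, choice, DDMParams(drift, params_up.boundary, params_up.bias, ndt)
            )
        for k in range(4):
            expected += stats.norm.logpdf(theta[cell, k], mu[0, k], sigma[0, k])
    for k, name in enumerate(PARAM_NAMES):
        expected += stats.norm.logpdf(mu[0, k], spec.prior_mean_loc[name], spec.prior_mean_scale[name])
        expected += -0.5 * (sigma[0, k] / spec.prior_sd_scale) ** 2

    assert model.log_density(theta, mu, sigma) == pytest.approx(expected, abs=1e-8)


def test_posterior_summary_constant_draws_and_credibility_rule():
    s = summarize_draws(np.full(100, 1.7))
    assert s.sd == pytest.approx(0.0, abs=1e-12)
    assert s.ci_low == s.ci_high == pytest.approx(s.mean, abs=1e-12)
    assert s.credible
    spanning = summarize_draws(np.linspace(-1, 1, 200))
    assert not spanning.credible
    assert spanning.ci_low <= spanning.mean <= spanning.ci_high


def test_tight_priors_dominate_posterior():
    cfg = CohortConfig(
        n_participants=4, conditions=TWO_CONDITIONS[:1],
        session_missing_prob=0.0, contaminant_rate=0.0, censor_at_deadline=False, seed=51,
    )
    trials, _ = generate_cohort(cfg)
    retained, _ = filter_trials(trials, expected_per_participant=60)
    loc = {"drift": 0.9, "bias_logit": -0.05, "boundary_log": 0.7, "ndt": 0.3}
    spec = ModelSpec(
        chains=2, warmup=250, draws=250, seed=8,
        prior_mean_loc=loc,
        prior_mean_scale={k: 1e-3 for k in loc},
    )
    res = fit(build_model(spec, retained))
    mu = res.mu_draws().mean(axis=0)[0]
    for k, name in enumerate(PARAM_NAMES):
        assert mu[k] == pytest.approx(loc[name], abs=5e-3)


def test_fit_seed_contract(clean_retained):
    spec = ModelSpec(chains=2, warmup=100, draws=100, seed=13)
    sub = clean_retained[clean_retained.participant_id <= 4]
    r1 = fit(build_model(spec, sub))
    r2 = fit(build_model(spec, sub))
    np.testing.assert_array_equal(r1.mu, r2.mu)
    np.testing.assert_array_equal(r1.sigma, r2.sigma)


def test_condition_summaries_and_backtransforms(small_fit):
    summ = condition_summaries(small_fit)
    assert (summ["ci_low"] <= summ["mean"]).all() and (summ["mean"] <= summ["ci_high"]).all()
    bias_rows = summ[summ.parameter == "bias_logit"]
    assert len(bias_rows) == 2  # one per change-probability level, single probe only
    assert (expit(bias_rows["mean"]) > 0).all() and (expit(bias_rows["mean"]) < 1).all()
    mu = small_fit.mu_draws()
    assert (np.exp(mu[:, :, PARAM_NAMES.index("boundary_log")]) > 0).all()


def test_contrast_per_draw_identity_and_antisymmetry(small_fit):
    cs = contrasts(small_fit)
    assert {c.contrast for c in cs} == {"change_prob"}  # only factor that varies
    c = cs[0]
    manip = _marginal_mean_draws(small_fit, "bias_logit", "change_prob", "high_80", "single_probe")
    base = _marginal_mean_draws(small_fit, "bias_logit", "change_prob", "low_50", "single_probe")
    diff = manip - base
    assert c.summary.mean == pytest.approx(diff.mean())
    reversed_summary = summarize_draws(base - manip)
    assert reversed_summary.mean == pytest.approx(-c.summary.mean)
    assert reversed_summary.ci_low == pytest.approx(-c.summary.ci_high)


def test_degenerate_hierarchy_concentrates_group_sds_near_zero():
    cfg = CohortConfig(
        n_participants=40, conditions=TWO_CONDITIONS,
        drift_sd=0.0, bias_logit_sd=0.0, boundary_log_sd=0.0, ndt_sd=0.0,
        age_drift_corr=0.0, session_missing_prob=0.0, contaminant_rate=0.0,
        censor_at_deadline=False, seed=5,
    )
    trials, _ = generate_cohort(cfg)
    retained, _ = filter_trials(trials, expected_per_participant=120)
    res = fit(build_model(ModelSpec(chains=2, warmup=600, draws=700, seed=3), retained))
    sig = res.sigma.reshape(-1, res.model.n_cond, 4)
    mass_below = (sig < 0.1).mean(axis=0)
    assert (mass_below > 0.8).all()


def test_study_scale_bias_contrast_recovered_credibly(study_scale_fit):
    """At the study's sample size, the +0.15 logit-bias shift from the high
    change-probability manipulation is detected as a credible positive contrast."""
    _, _, _, result = study_scale_fit
    c = [x for x in contrasts(result) if x.contrast == "change_prob"][0]
    assert c.summary.mean > 0
    assert c.summary.credible
    assert c.summary.mean == pytest.approx(0.15, abs=0.1)
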