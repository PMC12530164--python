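"""Synthetic cohort generator: schedules, trial composition, planted artifacts."""

import numpy as np
import pandas as pd
import pytest

from ambddm import CohortConfig, ConditionKey, generate_cohort, make_schedule, trial_truths
from ambddm.cohort import ALL_CONDITIONS, HIGH, LOW, LONG, MINIMAL, SHORT, SINGLE, URGENT, WHOLE


def test_sixteen_distinct_conditions_with_unique_version_indices():
    idx = [c.version_index for c in ALL_CONDITIONS]
    assert sorted(idx) == list(range(1, 17))
    assert len(set(ALL_CONDITIONS)) == 16


def test_condition_key_levels_validated():
    with pytest.raises(ValueError):
        ConditionKey(study_time="short")


def test_schedule_empty_for_zero_participants():
    assert make_schedule(0, seed=1).empty


def test_schedule_completeness_and_daily_structure():
    sched = make_schedule(30, seed=2)
    for _, g in sched.groupby("participant_id"):
        assert sorted(g["version_index"]) == list(range(1, 17))
        assert g.groupby("day").size().eq(2).all()
        assert g["day"].max() == 8


def test_schedule_draws_from_pool_of_three_orderings():
    sched = make_schedule(30, seed=3)
    orders = {
        tuple(g.sort_values(["day", "slot"])["version_index"]) for _, g in sched.groupby("participant_id")
    }
    assert 1 <= len(orders) <= 3


@pytest.mark.parametrize(
    "change_prob,n_different", [(HIGH, 48), (LOW, 30)]
)
def test_trial_truth_composition_is_exact(change_prob, n_different):
    version = ConditionKey(SHORT, change_prob, MINIMAL, WHOLE)
    labels = trial_truths(version, seed=4)
    assert labels.size == 60
    assert (labels == "different").sum() == n_different


def test_trial_truths_seed_contract():
    version = ConditionKey(LONG, HIGH, URGENT, SINGLE)
    np.testing.assert_array_equal(trial_truths(version, seed=5), trial_truths(version, seed=5))
    assert (trial_truths(version, seed=5) != trial_truths(version, seed=6)).any()


def test_empty_cohort():
    trials, truth = generate_cohort(CohortConfig(n_participants=0))
    assert trials.empty and truth.empty


def test_config_validation():
    with pytest.raises(ValueError):
        CohortConfig(n_participants=-1)
    with pytest.raises(ValueError):
        CohortConfig(session_missing_prob=1.5)
    with pytest.raises(ValueError):
        CohortConfig(drift_sd=-0.1)


@pytest.fixture(scope="module")
def pristine_cohort():
    """No missingness, contaminants or censoring: every scheduled trial responded."""
    cfg = CohortConfig(
        n_participants=5,
        conditions=tuple(c for c in ALL_CONDITIONS if c.urgency == MINIMAL)[:4],
        session_missing_prob=0.0,
        contaminant_rate=0.0,
        censor_at_deadline=False,
        seed=11,
    )
    return cfg, *generate_cohort(cfg)


def test_pristine_cohort_has_every_scheduled_trial_responded(pristine_cohort):
    cfg, trials, truth = pristine_cohort
    assert len(trials) == cfg.n_participants * len(cfg.conditions) * 60
    assert (trials["response"] != "none").all()
    assert trials["rt_ms"].gt(0).all()
    assert len(truth) == cfg.n_participants * len(cfg.conditions)


def test_cohort_reproducible_from_config(pristine_cohort):
    cfg, trials, truth = pristine_cohort
    trials2, truth2 = generate_cohort(cfg)
    pd.testing.assert_frame_equal(trials, trials2)
    pd.testing.assert_frame_equal(truth, truth2)


def test_zero_noise_gives_identical_person_parameters():
    cfg = CohortConfig(
        n_participants=6,
        conditions=ALL_CONDITIONS[:2],
        drift_sd=0.0, bias_logit_sd=0.0, boundary_log_sd=0.0, ndt_sd=0.0,
        age_drift_corr=0.0,
        session_missing_prob=0.0, contaminant_rate=0.0, seed=12,
    )
    _, truth = generate_cohort(cfg)
    for vi, g in truth.groupby("version_index"):
        for col in ("drift", "bias_logit", "boundary_log", "ndt"):
            assert g[col].nunique() == 1
        expected = cfg.condition_mean([c for c in cfg.conditions if c.version_index == vi][0])
        np.testing.assert_allclose(
            g[["drift", "bias_logit", "boundary_log", "ndt"]].iloc[0], expected
        )


def test_planted_contaminants_lie_outside_retention_bounds():
    cfg = CohortConfig(
        n_participants=8,
        conditions=tuple(c for c in ALL_CONDITIONS if c.urgency == MINIMAL)[:4],
        session_missing_prob=0.0,
        contaminant_rate=0.02,
        censor_at_deadline=False,
        seed=13,
    )
    trials, _ = generate_cohort(cfg)
    contam = trials[trials["is_contaminant"]]
    assert len(contam) > 0
    assert ((contam["rt_ms"] < 200) | (contam["rt_ms"] > 7000)).all()


def test_deadline_censoring_marks_responses_none():
    cfg = CohortConfig(
        n_participants=6,
        conditions=tuple(c for c in ALL_CONDITIONS if c.urgency == URGENT)[:2],
        session_missing_prob=0.0, contaminant_rate=0.0, seed=14,
    )
    trials, _ = generate_cohort(cfg)
    censored = trials["response"] == "none"
    assert censored.any()
    assert trials.loc[censored, "rt_ms"].isna().all()
    assert trials.loc[~censored, "rt_ms"].le(3000).all()


def test_session_missingness_rate_near_target_across_seeds():
    rates = []
    for seed in range(6):
        cfg = CohortConfig(
            n_participants=20, contaminant_rate=0.0, trials_per_version=60, seed=100 + seed
        )
        trials, _ = generate_cohort(cfg)
        scheduled = 20 * 16 * 60
        rates.append(1.0 - len(trials) / scheduled)
    assert abs(np.mean(rates) - 0.0845) < 0.01


def test_age_drift_correlation_near_target():
    corrs = []
    for seed in range(3):
        cfg = CohortConfig(
            n_participants=68,
            conditions=ALL_CONDITIONS[:1],
            session_missing_prob=0.0, contaminant_rate=0.0, seed=200 + seed,
        )
        _, truth = generate_cohort(cfg)
        per = truth.groupby("participant_id").first()
        corrs.append(np.corrcoef(per["age"], per["drift"])[0, 1])
    assert abs(np.mean(corrs) - (-0.45)) < 0.1


def test_ground_truth_table_carries_condition_means():
    cfg = CohortConfig(n_participants=0)
    tg = cfg.true_group_means()
    assert len(tg) == 16
    # factor-to-parameter mapping: drift keyed by study time, bias by change
    # probability, boundary by urgency (within probe type)
    short_whole = tg[(tg.study_time == SHORT) & (tg.probe_type == WHOLE)]
    assert (short_whole["drift"] == 1.65).all()
    high_single = tg[(tg.change_prob == HIGH) & (tg.probe_type == SINGLE)]
    assert (high_single["bias_logit"] == 0.10).all()
    urgent_single = tg[(tg.urgency == URGENT) & (tg.probe_type == SINGLE)]
    assert (urgent_single["boundary_log"] == 0.66).all()
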