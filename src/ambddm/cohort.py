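"""Synthetic study-cohort generator for the factorial change-detection task.

Emulates an ambulatory visual working-memory (change detection / feature
binding) study: each participant works through 16 task versions — a
2 (study time: 500/2000 ms) x 2 (change probability: 50%/80% *different*)
x 2 (choice urgency: 10,000/3000 ms response deadline) x 2 (probe type:
whole display / single probe) within-person factorial — two versions per day
over 8 days, 60 trials per version. Trials are simulated from known
ground-truth diffusion parameters so that every downstream stage (filtering,
hierarchical fitting, posterior predictive checks, correlations) can be
tested against a known data-generating process.

Realism knobs mirror the observed data stream: whole sessions go unrecorded,
responses slower than the version's deadline are recorded without a response,
and a small fraction of recorded RTs are contaminants outside the plausible
200-7000 ms window (technical errors, lapses).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .wiener import DDMParams, sample_trials

__all__ = [
    "ConditionKey",
    "CohortConfig",
    "ALL_CONDITIONS",
    "TRIAL_COLUMNS",
    "make_schedule",
    "trial_truths",
    "generate_cohort",
]

SHORT, LONG = "short_500ms", "long_2000ms"
LOW, HIGH = "low_50", "high_80"
MINIMAL, URGENT = "minimal_10000ms", "high_3000ms"
WHOLE, SINGLE = "whole_display", "single_probe"


@dataclass(frozen=True, order=True)
class ConditionKey:
    """The four binary task factors identifying one of the 16 versions."""

    study_time: str = SHORT
    change_prob: str = LOW
    urgency: str = MINIMAL
    probe_type: str = WHOLE

    def __post_init__(self):
        for f, levels in (
            ("study_time", (SHORT, LONG)),
            ("change_prob", (LOW, HIGH)),
            ("urgency", (MINIMAL, URGENT)),
            ("probe_type", (WHOLE, SINGLE)),
        ):
            if getattr(self, f) not in levels:
                raise ValueError(f"{f} must be one of {levels}")

    @property
    def study_time_ms(self) -> int:
        return 500 if self.study_time == SHORT else 2000

    @property
    def deadline_ms(self) -> int:
        return 10_000 if self.urgency == MINIMAL else 3_000

    @property
    def p_different(self) -> float:
        return 0.5 if self.change_prob == LOW else 0.8

    @property
    def version_index(self) -> int:
        """Canonical 1..16 version number (study, change, urgency, probe nested)."""
        return (
            8 * (self.study_time == LONG)
            + 4 * (self.change_prob == HIGH)
            + 2 * (self.urgency == URGENT)
            + (self.probe_type == SINGLE)
            + 1
        )


ALL_CONDITIONS: tuple[ConditionKey, ...] = tuple(
    ConditionKey(s, c, u, p)
    for s, c, u, p in itertools.product((SHORT, LONG), (LOW, HIGH), (MINIMAL, URGENT), (WHOLE, SINGLE))
)

#: Long-format trial table schema (one row per recorded trial).
TRIAL_COLUMNS = [
    "participant_id",
    "age",
    "day",
    "version_index",
    "study_time_ms",
    "change_prob",
    "deadline_ms",
    "probe_type",
    "trial_index",
    "truth",
    "response",
    "rt_ms",
    "is_contaminant",
]

_PARAM_NAMES = ("drift", "bias_logit", "boundary_log", "ndt")


@dataclass
class CohortConfig:
    """Ground-truth generative settings, on each parameter's sampling scale.

    Condition-cell means are assembled from per-factor tables: drift depends on
    (study time, probe type), logit bias on (change probability, probe type),
    log boundary on (urgency, probe type); nondecision time is constant. The
    defaults are the fitted group-level magnitudes of the motivating study,
    so recovery tests exercise realistic effect sizes. Between-person spread is
    a person-level offset per parameter, shared across conditions; the drift
    offset is constructed jointly with age to hit ``age_drift_corr``.
    """

    n_participants: int = 68
    conditions: tuple[ConditionKey, ...] = ALL_CONDITIONS
    trials_per_version: int = 60

    # group means on sampling scales
    drift_mean: dict = field(
        default_factory=lambda: {
            (SHORT, WHOLE): 1.65, (LONG, WHOLE): 1.37,
            (SHORT, SINGLE): 0.88, (LONG, SINGLE): 0.90,
        }
    )
    bias_logit_mean: dict = field(
        default_factory=lambda: {
            (LOW, WHOLE): 0.07, (HIGH, WHOLE): 0.13,
            (LOW, SINGLE): -0.05, (HIGH, SINGLE): 0.10,
        }
    )
    boundary_log_mean: dict = field(
        default_factory=lambda: {
            (MINIMAL, WHOLE): 0.92, (URGENT, WHOLE): 0.91,
            (MINIMAL, SINGLE): 0.71, (URGENT, SINGLE): 0.66,
        }
    )
    ndt_mean: float = 0.35  # seconds

    # between-person SDs on sampling scales
    drift_sd: float = 0.45
    bias_logit_sd: float = 0.25
    boundary_log_sd: float = 0.20
    ndt_sd: float = 0.08

    # covariate model
    age_mean: float = 49.0
    age_sd: float = 14.0
    age_range: tuple[float, float] = (24.0, 80.0)
    age_drift_corr: float = -0.45

    # data-stream imperfections
    session_missing_prob: float = 0.0845
    trial_missing_prob: float = 0.0
    contaminant_rate: float = 54 / 59_762
    contaminant_fast_ms: tuple[float, float] = (50.0, 199.0)
    contaminant_slow_ms: tuple[float, float] = (7001.0, 9500.0)
    censor_at_deadline: bool = True
    record_deadline_rt: bool = False  # robustness knob: keep rt at the deadline

    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        for name in ("drift_sd", "bias_logit_sd", "boundary_log_sd", "ndt_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("session_missing_prob", "trial_missing_prob", "contaminant_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not -1.0 <= self.age_drift_corr <= 1.0:
            raise ValueError("age_drift_corr must lie in [-1, 1]")
        self.conditions = tuple(
            c if isinstance(c, ConditionKey) else ConditionKey(**c) for c in self.conditions
        )
        # accept "level|probe" string keys (YAML/JSON form) alongside tuples
        for name in ("drift_mean", "bias_logit_mean", "boundary_log_mean"):
            d = getattr(self, name)
            setattr(
                self,
                name,
                {(tuple(k.split("|")) if isinstance(k, str) else tuple(k)): float(v) for k, v in d.items()},
            )

    def condition_mean(self, cond: ConditionKey) -> np.ndarray:
        return np.array(
            [
                self.drift_mean[(cond.study_time, cond.probe_type)],
                self.bias_logit_mean[(cond.change_prob, cond.probe_type)],
                self.boundary_log_mean[(cond.urgency, cond.probe_type)],
                self.ndt_mean,
            ]
        )

    def true_group_means(self) -> pd.DataFrame:
        """Ground-truth group mean per condition on the sampling scales."""
        rows = [
            {"version_index": c.version_index, **asdict(c),
             **dict(zip(_PARAM_NAMES, self.condition_mean(c)))}
            for c in self.conditions
        ]
        return pd.DataFrame(rows).set_index("version_index").sort_index()

    def to_dict(self) -> dict:
        """JSON/YAML-ready form: tuple keys joined as "level|probe" strings."""
        d = asdict(self)
        d["conditions"] = [asdict(c) for c in self.conditions]
        for name in ("drift_mean", "bias_logit_mean", "boundary_log_mean"):
            d[name] = {"|".join(k): v for k, v in getattr(self, name).items()}
        return d


def make_schedule(n_participants: int, seed, conditions=ALL_CONDITIONS) -> pd.DataFrame:
    """Assign every version once per participant, two versions per day.

    The orderings are drawn from a pool of 3 fixed permutations generated from
    the seed; each participant gets one of the 3 schedules uniformly at random
    (whether the original schedules were counterbalanced is not documented, so
    no balancing is imposed). Returns columns
    (participant_id, day, slot, version_index).
    """
    if n_participants < 0:
        raise ValueError("n_participants must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    versions = np.array([c.version_index for c in conditions])
    pool = [rng.permutation(versions) for _ in range(3)]
    rows = []
    for pid in range(1, n_participants + 1):
        order = pool[rng.integers(3)]
        for i, v in enumerate(order):
            rows.append((pid, i // 2 + 1, i % 2 + 1, int(v)))
    return pd.DataFrame(rows, columns=["participant_id", "day", "slot", "version_index"])


def trial_truths(version: ConditionKey, seed) -> np.ndarray:
    """60 trial labels with the version's exact same/different composition.

    High change probability means exactly 48 *different* / 12 *same* trials;
    low means 30/30. The composition is fixed (the schedules were built from
    fixed trial counts, not per-trial coin flips); only the order is random.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_diff = 48 if version.change_prob == HIGH else 30
    labels = np.array(["different"] * n_diff + ["same"] * (60 - n_diff))
    return rng.permutation(labels)


def _truncnorm(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full study dataset plus its ground-truth parameter table.

    Returns ``(trials, truth)``:

    * ``trials`` — long-format recorded trials (:data:`TRIAL_COLUMNS`). Trials
      from skipped sessions are simply absent; deadline-exceeding responses are
      present with ``response='none'`` and no RT.
    * ``truth`` — one row per (participant, condition) with the person-condition
      parameters on the sampling scales, plus age and the person offsets.
    """
    rng = np.random.default_rng(config.seed)
    conditions = sorted(config.conditions, key=lambda c: c.version_index)
    n = config.n_participants

    schedule = make_schedule(n, rng, conditions)

    # ages and person-level offsets (z-scores); drift offset tied to age
    age = _truncnorm(rng, config.age_mean, config.age_sd, *config.age_range, size=n)
    z_age = (age - config.age_mean) / config.age_sd
    rho = config.age_drift_corr
    z = rng.standard_normal((n, 4))
    z[:, 0] = rho * z_age + np.sqrt(max(0.0, 1 - rho**2)) * z[:, 0]
    sds = np.array([config.drift_sd, config.bias_logit_sd, config.boundary_log_sd, config.ndt_sd])
    offsets = z * sds

    truth_rows = []
    trial_frames = []
    cond_by_version = {c.version_index: c for c in conditions}
    tpv = config.trials_per_version

    for pid in range(1, n + 1):
        pid_sched = schedule[schedule.participant_id == pid]
        for _, srow in pid_sched.iterrows():
            cond = cond_by_version[srow.version_index]
            theta = config.condition_mean(cond) + offsets[pid - 1]
            theta[3] = max(theta[3], 0.05)  # nondecision time stays physical
            truth_rows.append(
                {
                    "participant_id": pid,
                    "age": age[pid - 1],
                    "version_index": cond.version_index,
                    **dict(zip(_PARAM_NAMES, theta)),
                }
            )
            if rng.random() < config.session_missing_prob:
                continue  # whole version unrecorded

            truths = trial_truths(cond, rng)
            sign = np.where(truths == "different", 1.0, -1.0)
            params = DDMParams(
                drift=theta[0],
                boundary=float(np.exp(theta[2])),
                bias=float(1.0 / (1.0 + np.exp(-theta[1]))),
                ndt=theta[3],
            )
            # one sampler call per drift sign (stimulus coding)
            rt_s = np.empty(tpv)
            up = np.empty(tpv, dtype=bool)
            for s_val in (1.0, -1.0):
                idx = np.flatnonzero(sign == s_val)
                if idx.size == 0:
                    continue
                p = DDMParams(params.drift * s_val, params.boundary, params.bias, params.ndt)
                c_up, c_rt = sample_trials(p, idx.size, rng)
                up[idx] = c_up
                rt_s[idx] = c_rt

            rt_ms = rt_s * 1000.0
            response = np.where(up, "different", "same").astype(object)
            censored = config.censor_at_deadline & (rt_ms > cond.deadline_ms)
            is_contam = np.zeros(tpv, dtype=bool)
            responded = ~censored
            k = rng.binomial(responded.sum(), config.contaminant_rate)
            if k:
                pick = rng.choice(np.flatnonzero(responded), size=k, replace=False)
                for j in pick:
                    slow_ok = cond.deadline_ms > config.contaminant_slow_ms[1]
                    if slow_ok and rng.random() < 0.5:
                        rt_ms[j] = rng.uniform(*config.contaminant_slow_ms)
                    else:
                        rt_ms[j] = rng.uniform(*config.contaminant_fast_ms)
                    is_contam[j] = True

            rt_out = rt_ms.copy()
            resp_out = response.copy()
            if config.censor_at_deadline:
                resp_out[censored] = "none"
                rt_out[censored] = cond.deadline_ms if config.record_deadline_rt else np.nan
            keep = np.ones(tpv, dtype=bool)
            if config.trial_missing_prob > 0:
                keep = rng.random(tpv) >= config.trial_missing_prob

            frame = pd.DataFrame(
                {
                    "participant_id": pid,
                    "age": age[pid - 1],
                    "day": srow.day,
                    "version_index": cond.version_index,
                    "study_time_ms": cond.study_time_ms,
                    "change_prob": cond.change_prob,
                    "deadline_ms": cond.deadline_ms,
                    "probe_type": cond.probe_type,
                    "trial_index": np.arange(1, tpv + 1),
                    "truth": truths,
                    "response": resp_out,
                    "rt_ms": rt_out,
                    "is_contaminant": is_contam,
                }
            )
            trial_frames.append(frame[keep])

    trials = (
        pd.concat(trial_frames, ignore_index=True)
        if trial_frames
        else pd.DataFrame(columns=TRIAL_COLUMNS)
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["participant_id", "age", "version_index", *_PARAM_NAMES],
    )
    return trials, truth
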