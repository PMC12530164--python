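"""Trial-retention rules and engagement/accuracy summaries.

Retention follows the study's fixed real-world cutoffs: trials that exceeded
their version's response deadline are recorded without a response and
excluded first; of the responded trials, RTs *faster than* 200 ms or *slower
than* 7000 ms are excluded (strict inequalities — exactly 200 or 7000 ms is
retained). All report percentages use the scheduled trial count as the
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ExclusionReport",
    "filter_trials",
    "accuracy_summary",
    "engagement_summary",
    "RT_MIN_MS",
    "RT_MAX_MS",
    "EXPECTED_TRIALS",
]

RT_MIN_MS = 200.0
RT_MAX_MS = 7000.0
EXPECTED_TRIALS = 960  # 16 versions x 60 trials


@dataclass(frozen=True)
class ExclusionReport:
    """Conservation accounting of scheduled trials through the retention rules."""

    scheduled: int
    recorded: int
    unrecorded: int
    deadline_excluded: int
    rt_bound_excluded: int
    retained: int

    def __post_init__(self):
        assert self.scheduled == self.recorded + self.unrecorded
        assert self.retained == self.recorded - self.deadline_excluded - self.rt_bound_excluded
        assert min(asdict(self).values()) >= 0

    def rates(self) -> dict:
        """Each count as % of scheduled, rounded to 2 decimals."""
        denom = self.scheduled if self.scheduled else 1
        return {
            f"{k}_pct": round(100.0 * v / denom, 2)
            for k, v in asdict(self).items()
            if k != "scheduled"
        }

    def to_dict(self) -> dict:
        return {**asdict(self), **self.rates()}


def filter_trials(
    records: pd.DataFrame,
    expected_per_participant: int = EXPECTED_TRIALS,
    rt_min_ms: float = RT_MIN_MS,
    rt_max_ms: float = RT_MAX_MS,
    n_participants: int | None = None,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the retention rules; return (retained trials, exclusion report).

    ``records`` holds recorded trials only — unrecorded trials are inferred as
    scheduled minus recorded, with scheduled = n_participants x
    ``expected_per_participant``. Deadline-exceeding trials are rows with
    ``response == 'none'``; they are excluded before the RT-bound rule so no
    trial is double-counted.
    """
    if n_participants is None:
        n_participants = records["participant_id"].nunique()
    scheduled = n_participants * expected_per_participant
    recorded = len(records)
    if recorded > scheduled:
        raise ValueError("more recorded trials than scheduled")

    responded = records["response"] != "none"
    rt = records.loc[responded, "rt_ms"]
    if (rt < 0).any() or rt.isna().any():
        raise ValueError("responded trials must carry a nonnegative rt_ms")

    deadline_excluded = int((~responded).sum())
    out_of_bounds = responded & ((records["rt_ms"] < rt_min_ms) | (records["rt_ms"] > rt_max_ms))
    retained = records[responded & ~out_of_bounds].copy()

    report = ExclusionReport(
        scheduled=scheduled,
        recorded=recorded,
        unrecorded=scheduled - recorded,
        deadline_excluded=deadline_excluded,
        rt_bound_excluded=int(out_of_bounds.sum()),
        retained=len(retained),
    )
    return retained, report


def accuracy_summary(retained: pd.DataFrame) -> pd.DataFrame:
    """Correct count, total, accuracy % and mean RT, per probe type and overall.

    A trial is correct iff the response matches the trial truth. Accuracy is
    reported to 2 decimals; mean RT is over all retained trials, correct and
    incorrect alike.
    """
    if retained.empty:
        return pd.DataFrame(columns=["probe_type", "correct", "total", "accuracy_pct", "mean_rt_ms"])
    df = retained.assign(correct=(retained["response"] == retained["truth"]))
    rows = []
    groups = [("overall", df)] + [(k, g) for k, g in df.groupby("probe_type")]
    for name, g in groups:
        rows.append(
            {
                "probe_type": name,
                "correct": int(g["correct"].sum()),
                "total": len(g),
                "accuracy_pct": round(100.0 * g["correct"].mean(), 2),
                "mean_rt_ms": round(float(g["rt_ms"].mean()), 2),
            }
        )
    return pd.DataFrame(rows)


def engagement_summary(
    records: pd.DataFrame,
    expected_per_participant: int = EXPECTED_TRIALS,
    trials_per_version: int = 60,
) -> pd.DataFrame:
    """Distribution of participants by study completion.

    A version counts as completed when at least one of its trials was
    recorded. Completion % is recorded trials / expected, to 1 decimal. The
    output mirrors the engagement table layout: one row per observed
    completion level, with participant counts and percentages.
    """
    if records.empty:
        return pd.DataFrame(
            columns=["completion_pct", "trials_completed", "versions_completed", "participants", "participants_pct"]
        )
    per = records.groupby("participant_id").agg(
        trials_completed=("trial_index", "size"),
        versions_completed=("version_index", "nunique"),
    )
    per["completion_pct"] = (100.0 * per["trials_completed"] / expected_per_participant).round(1)
    n_total = per.shape[0]
    hist = (
        per.groupby(["completion_pct", "trials_completed", "versions_completed"])
        .size()
        .rename("participants")
        .reset_index()
        .sort_values("completion_pct", ascending=False, ignore_index=True)
    )
    hist["participants_pct"] = (100.0 * hist["participants"] / n_total).round(0).astype(int)
    return hist
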