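"""Fit the multilevel DDM to a simulated cohort and test the manipulations.

Generates a cohort in which the high change-probability condition shifts the
start point toward 'different' (+0.15 on the logit scale), fits the
hierarchical model, and summarizes the manipulation-minus-baseline contrast
with the 95% credible-interval rule.
"""

import warnings

from ambddm import (
    CohortConfig, ConditionKey, ModelSpec, build_model, condition_summaries,
    contrasts, filter_trials, fit, generate_cohort,
)
from ambddm.cohort import HIGH, LOW, MINIMAL, SHORT, SINGLE

warnings.filterwarnings("ignore", message="MCMC diagnostics")

conditions = tuple(ConditionKey(SHORT, c, MINIMAL, SINGLE) for c in (LOW, HIGH))
# the study's sample size: between-person variability dominates the contrast's
# precision, so detecting a +0.15 logit shift needs the full cohort
cfg = CohortConfig(
    n_participants=68, conditions=conditions,
    session_missing_prob=0.0, contaminant_rate=0.0, censor_at_deadline=False, seed=3,
)
trials, truth = generate_cohort(cfg)
retained, _ = filter_trials(trials, expected_per_participant=120)
print(f"fitting {len(retained)} trials from {cfg.n_participants} participants ...")

spec = ModelSpec(chains=2, warmup=500, draws=500, seed=11)
result = fit(build_model(spec, retained))
print(f"max split R-hat {result.rhat_max:.3f}, min ESS {result.ess_min:.0f}")

print("\nmarginal posterior summaries (sampling scales):")
print(condition_summaries(result).to_string(index=False))

print("\ncontrasts (manipulated - baseline):")
for c in contrasts(result):
    s = c.summary
    print(
        f"  {c.contrast:>12} on {c.parameter:>12} [{c.probe_type}]: "
        f"{s.mean:+.3f} (95% CI {s.ci_low:+.3f} to {s.ci_high:+.3f}) "
        f"{'credible' if s.credible else 'not credible'}"
    )
# the change-probability contrast on logit bias should land near the
# generative +0.15 and be flagged credible at this sample size
print(f"\ngenerative logit-bias contrast: "
      f"{cfg.bias_logit_mean[(HIGH, SINGLE)] - cfg.bias_logit_mean[(LOW, SINGLE)]:+.2f}")
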