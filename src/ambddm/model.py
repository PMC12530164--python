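"""Multilevel Bayesian drift diffusion model for the factorial task.

Each person x condition cell carries four diffusion parameters, sampled on
the scales used throughout: drift (natural), initial bias (logit), boundary
separation (log) and nondecision time (seconds, natural). Person-condition
values are exchangeable draws from condition-level normal distributions,

    theta[i, c, k] ~ Normal(mu[c, k], sigma[c, k]),

and all parameters — person-condition values, condition means and SDs — are
estimated jointly in one MCMC run. Response coding is *stimulus coding*: the
upper boundary is the "different" response, and the condition-level drift
magnitude enters each trial's likelihood with a positive sign on *different*
trials and negated on *same* trials, so that a condition-level start-point
bias toward "different" is meaningful.

Sampling uses an adaptive componentwise Metropolis-within-Gibbs scheme:
person-condition cells are updated against their trial likelihood (numba
kernel), condition means by their conjugate normal full conditionals, and
condition SDs by an adaptive random-walk step on the log scale. Proposal
scales adapt toward a 0.44 acceptance rate during warmup only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import arviz as az
import numpy as np
import pandas as pd

from ._kernels import _SERIES_ERR, cell_loglik, group_interweave, init_cell_logliks, mwg_sweep
from .cohort import ConditionKey, HIGH, LOW, LONG, SHORT, MINIMAL, URGENT

__all__ = [
    "PARAM_NAMES",
    "CONTRAST_DEFS",
    "ModelSpec",
    "PosteriorSummary",
    "ContrastResult",
    "HierarchicalDDM",
    "FitResult",
    "build_model",
    "fit",
    "condition_summaries",
    "contrasts",
    "summarize_draws",
]

PARAM_NAMES = ("drift", "bias_logit", "boundary_log", "ndt")

#: contrast name -> (matched parameter, factor field, manipulated level, baseline level)
CONTRAST_DEFS = {
    "study_time": ("drift", "study_time", LONG, SHORT),
    "change_prob": ("bias_logit", "change_prob", HIGH, LOW),
    "urgency": ("boundary_log", "urgency", URGENT, MINIMAL),
}


@dataclass
class ModelSpec:
    """Priors, parameterization flags and sampler settings.

    Group-mean priors are weakly informative on each sampling scale; the
    nondecision-time group mean is truncated at zero. ``vary_by_condition``
    lists the parameters given separate condition-level means ("no
    constraints" across the 16 cells by default); the rest share one pooled
    mean. ``fixed_params`` pins a parameter to a constant on its sampling
    scale (e.g. ``{"bias_logit": 0.0}`` for a no-bias model), which is how
    misspecified variants are built for sensitivity checks.
    """

    vary_by_condition: tuple[str, ...] = PARAM_NAMES
    fixed_params: dict = field(default_factory=dict)
    prior_mean_loc: dict = field(
        default_factory=lambda: {"drift": 0.0, "bias_logit": 0.0, "boundary_log": 0.0, "ndt": 0.3}
    )
    prior_mean_scale: dict = field(
        default_factory=lambda: {"drift": 3.0, "bias_logit": 1.5, "boundary_log": 1.5, "ndt": 0.3}
    )
    prior_sd_scale: float = 1.0  # half-normal scale for group SDs
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    rhat_threshold: float = 1.01
    ess_threshold: float = 400.0
    store_person_draws: bool = True

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("chains must be >= 2")
        if self.draws < 1 or self.warmup < 0:
            raise ValueError("draws must be >= 1 and warmup >= 0")
        if min(self.prior_mean_scale.values()) <= 0 or self.prior_sd_scale <= 0:
            raise ValueError("prior scales must be positive")
        for name in self.fixed_params:
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r}")


@dataclass(frozen=True)
class PosteriorSummary:
    """Mean, SD and central 95% credible interval of a scalar posterior."""

    mean: float
    sd: float
    ci_low: float
    ci_high: float

    @property
    def credible(self) -> bool:
        """True when 0 falls outside the central 95% credible interval."""
        return not (self.ci_low <= 0.0 <= self.ci_high)

    def to_dict(self) -> dict:
        return {**asdict(self), "credible": self.credible}


def summarize_draws(draws: np.ndarray) -> PosteriorSummary:
    draws = np.asarray(draws, float).ravel()
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return PosteriorSummary(
        mean=float(draws.mean()), sd=float(draws.std(ddof=1)) if draws.size > 1 else 0.0,
        ci_low=float(lo), ci_high=float(hi),
    )


@dataclass(frozen=True)
class ContrastResult:
    """Posterior of a manipulated-minus-baseline difference within a probe type."""

    parameter: str
    contrast: str
    probe_type: str
    summary: PosteriorSummary

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "contrast": self.contrast,
            "probe_type": self.probe_type,
            **self.summary.to_dict(),
        }


class HierarchicalDDM:
    """Prepared data and priors for one model fit.

    Holds trial arrays sorted by person-condition cell, the condition keys, and
    the effective group structure implied by the spec's parameterization flags.
    """

    def __init__(self, spec: ModelSpec, records: pd.DataFrame):
        if records.empty:
            raise ValueError("no trials to fit")
        rt_s = records["rt_ms"].to_numpy(float) / 1000.0
        if (rt_s <= 0).any() or np.isnan(rt_s).any():
            raise ValueError("all retained trials must have positive RTs")

        self.spec = spec
        df = records.copy()
        df["rt_s"] = rt_s
        conds = sorted(
            {
                ConditionKey(st, cp, ur, pt)
                for st, cp, ur, pt in zip(
                    df["study_time_ms"].map({500: SHORT, 2000: LONG}),
                    df["change_prob"],
                    df["deadline_ms"].map({10_000: MINIMAL, 3_000: URGENT}),
                    df["probe_type"],
                )
            },
            key=lambda c: c.version_index,
        )
        self.conditions: list[ConditionKey] = conds
        vidx = {c.version_index: i for i, c in enumerate(conds)}
        df["_cond"] = df["version_index"].map(vidx)
        df = df.sort_values(["participant_id", "_cond"], kind="stable")

        self.persons = np.array(sorted(df["participant_id"].unique()))
        cell_keys, cell_starts = np.unique(
            df[["participant_id", "_cond"]].to_numpy(), axis=0, return_index=True
        )
        order = np.argsort(cell_starts)
        cell_keys = cell_keys[order]
        starts = np.sort(cell_starts)
        self.cell_person = cell_keys[:, 0]
        self.cell_cond = cell_keys[:, 1].astype(np.int64)
        self.cell_ptr = np.concatenate([starts, [len(df)]]).astype(np.int64)
        self.rt = df["rt_s"].to_numpy()
        self.is_upper = (df["response"] == "different").to_numpy().astype(np.bool_)
        self.sign = np.where(df["truth"] == "different", 1.0, -1.0)
        self.min_rt = np.array(
            [self.rt[self.cell_ptr[c]:self.cell_ptr[c + 1]].min() for c in range(len(self.cell_cond))]
        )
        self.n_cells = len(self.cell_cond)
        self.n_cond = len(conds)

        # effective group index per (condition, parameter); pooled when the
        # parameter does not vary by condition
        self.group_of = np.zeros((self.n_cond, 4), dtype=np.int64)
        for k, name in enumerate(PARAM_NAMES):
            self.group_of[:, k] = (
                np.arange(self.n_cond) if name in spec.vary_by_condition else 0
            )
        self.update_mask = np.array(
            [name not in spec.fixed_params for name in PARAM_NAMES], dtype=bool
        )
        # cell index lists per (parameter, effective group)
        self.group_cells = {
            k: {
                int(g): np.flatnonzero(
                    np.isin(self.cell_cond, np.flatnonzero(self.group_of[:, k] == g))
                ).astype(np.int64)
                for g in np.unique(self.group_of[:, k])
            }
            for k in range(4)
        }
        self.m0 = np.array([spec.prior_mean_loc[n] for n in PARAM_NAMES])
        self.s0 = np.array([spec.prior_mean_scale[n] for n in PARAM_NAMES])

    # -- log densities -----------------------------------------------------
    def data_loglik(self, theta: np.ndarray) -> float:
        """Summed trial log likelihood at person-condition values ``theta``."""
        total = 0.0
        for c in range(self.n_cells):
            drift = theta[c, 0]
            bias = 1.0 / (1.0 + np.exp(-theta[c, 1]))
            boundary = np.exp(theta[c, 2])
            total += cell_loglik(
                self.rt, self.is_upper, self.sign,
                self.cell_ptr[c], self.cell_ptr[c + 1],
                drift, boundary, bias, theta[c, 3], _SERIES_ERR,
            )
        return float(total)

    def log_density(self, theta: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
        """Joint log density: likelihood + hierarchy + group priors (unnormalized
        only through the truncation constant of the nondecision-time mean)."""
        lp = self.data_loglik(theta)
        for c in range(self.n_cells):
            ci = self.cell_cond[c]
            for k in range(4):
                if not self.update_mask[k]:
                    continue
                s = sigma[ci, k]
                lp += -0.5 * ((theta[c, k] - mu[ci, k]) / s) ** 2 - np.log(s) - 0.5 * np.log(2 * np.pi)
        for k in range(4):
            if not self.update_mask[k]:
                continue
            for g in np.unique(self.group_of[:, k]):
                ci = int(np.flatnonzero(self.group_of[:, k] == g)[0])
                lp += -0.5 * ((mu[ci, k] - self.m0[k]) / self.s0[k]) ** 2 - np.log(self.s0[k]) - 0.5 * np.log(2 * np.pi)
                if PARAM_NAMES[k] == "ndt" and mu[ci, k] < 0:
                    return -np.inf
                lp += -0.5 * (sigma[ci, k] / self.spec.prior_sd_scale) ** 2
        return float(lp)

    # -- initialization ----------------------------------------------------
    def _init_state(self, rng: np.random.Generator):
        theta = np.empty((self.n_cells, 4))
        for c in range(self.n_cells):
            sl = slice(self.cell_ptr[c], self.cell_ptr[c + 1])
            correct = self.is_upper[sl] == (self.sign[sl] > 0)
            acc = np.clip(correct.mean(), 0.55, 0.95)
            a0 = 1.5
            theta[c] = (
                np.log(acc / (1 - acc)) / a0 + 0.2 * rng.standard_normal(),
                0.1 * rng.standard_normal(),
                np.log(a0) + 0.1 * rng.standard_normal(),
                min(0.3, 0.7 * self.min_rt[c]) * rng.uniform(0.8, 1.0),
            )
        for k, name in enumerate(PARAM_NAMES):
            if name in self.spec.fixed_params:
                theta[:, k] = self.spec.fixed_params[name]
        mu = np.empty((self.n_cond, 4))
        sigma = np.full((self.n_cond, 4), 0.3)
        sigma[:, 3] = 0.1
        for k in range(4):
            for g in np.unique(self.group_of[:, k]):
                sel = np.isin(self.cell_cond, np.flatnonzero(self.group_of[:, k] == g))
                mu[self.group_of[:, k] == g, k] = theta[sel, k].mean()
        return theta, mu, sigma


def build_model(spec: ModelSpec, records: pd.DataFrame) -> HierarchicalDDM:
    """Prepare a hierarchical DDM for preprocessed (retained) trials."""
    return HierarchicalDDM(spec, records)


@dataclass
class FitResult:
    """Posterior draws plus convergence diagnostics.

    Draw arrays have shape (chains, draws, ...); ``mu``/``sigma`` are indexed
    by condition and parameter, ``theta`` (if stored) by person-condition cell.
    """

    model: HierarchicalDDM
    spec: ModelSpec
    mu: np.ndarray
    sigma: np.ndarray
    theta: np.ndarray | None
    theta_mean: np.ndarray
    accept_rates: dict
    rhat_max: float
    ess_min: float
    converged: bool

    @property
    def conditions(self):
        return self.model.conditions

    def mu_draws(self) -> np.ndarray:
        """Group-mean draws flattened over chains: (samples, n_cond, 4)."""
        return self.mu.reshape(-1, *self.mu.shape[2:])

    def person_param_means(self, parameter: str, conditions=None) -> pd.Series:
        """Posterior-mean person-level parameter, averaged over ``conditions``.

        This is the person-level point estimate used for covariate analyses:
        the posterior mean of each person-condition value, averaged across the
        requested conditions (all conditions if None).
        """
        k = PARAM_NAMES.index(parameter)
        if conditions is None:
            keep = np.ones(self.model.n_cond, bool)
        else:
            want = {c.version_index for c in conditions}
            keep = np.array([c.version_index in want for c in self.model.conditions])
        vals = {}
        for p in self.model.persons:
            sel = (self.model.cell_person == p) & keep[self.model.cell_cond]
            if sel.any():
                vals[p] = float(self.theta_mean[sel, k].mean())
        return pd.Series(vals, name=parameter)

    def to_inferencedata(self) -> az.InferenceData:
        coords = {
            "condition": [c.version_index for c in self.model.conditions],
            "param": list(PARAM_NAMES),
        }
        data = {
            "group_mean": (["chain", "draw", "condition", "param"], self.mu),
            "group_sd": (["chain", "draw", "condition", "param"], self.sigma),
        }
        return az.from_dict(
            {k: v[1] for k, v in data.items()},
            dims={k: v[0][2:] for k, v in data.items()},
            coords=coords,
        )


def _update_groups(model: HierarchicalDDM, theta, mu, sigma, sig_scales, sig_acc, rng):
    """Gibbs/MH updates of condition means and SDs given person-condition values."""
    spec = model.spec
    for k in range(4):
        if not model.update_mask[k]:
            continue
        for g in np.unique(model.group_of[:, k]):
            conds = np.flatnonzero(model.group_of[:, k] == g)
            sel = np.isin(model.cell_cond, conds)
            vals = theta[sel, k]
            n = vals.size
            sig = sigma[conds[0], k]
            # conjugate normal mean update
            prec = n / sig**2 + 1.0 / model.s0[k] ** 2
            mean = (vals.sum() / sig**2 + model.m0[k] / model.s0[k] ** 2) / prec
            sd = 1.0 / np.sqrt(prec)
            m_new = rng.normal(mean, sd)
            if PARAM_NAMES[k] == "ndt":
                for _ in range(100):
                    if m_new >= 0:
                        break
                    m_new = rng.normal(mean, sd)
                m_new = abs(m_new)
            mu[conds, k] = m_new
            # random-walk update of log sigma
            ls_old = np.log(sig)
            ls_new = ls_old + sig_scales[g, k] * rng.standard_normal()
            sig_new = np.exp(ls_new)
            ssq = ((vals - m_new) ** 2).sum()
            def _lt(s, ls):
                return (
                    -n * ls
                    - ssq / (2 * s**2)
                    - s**2 / (2 * spec.prior_sd_scale**2)
                    + ls  # Jacobian of the log transform
                )
            if sig_new > 1e-4 and np.log(rng.random()) < _lt(sig_new, ls_new) - _lt(sig, ls_old):
                sigma[conds, k] = sig_new
                sig_acc[g, k] = 1.0
            else:
                sig_acc[g, k] = 0.0


def fit(model: HierarchicalDDM, spec: ModelSpec | None = None) -> FitResult:
    """Run the MCMC and attach convergence diagnostics.

    Nonconvergence (split R-hat above the threshold, or effective sample size
    below it, on any condition-level parameter) is reported as a warning and
    in ``FitResult.converged``; draws are returned either way.
    """
    spec = spec or model.spec
    n_keep = spec.draws
    n_iter = spec.warmup + n_keep
    children = np.random.SeedSequence(spec.seed).spawn(spec.chains)

    mu_out = np.empty((spec.chains, n_keep, model.n_cond, 4))
    sig_out = np.empty_like(mu_out)
    th_out = (
        np.empty((spec.chains, n_keep, model.n_cells, 4)) if spec.store_person_draws else None
    )
    th_mean = np.zeros((model.n_cells, 4))
    acc_tot = np.zeros((model.n_cells, 4))

    update_mask = model.update_mask
    for ch in range(spec.chains):
        rng = np.random.default_rng(children[ch])
        theta, mu, sigma = model._init_state(rng)
        cur_ll = init_cell_logliks(
            model.rt, model.is_upper, model.sign, model.cell_ptr, theta, _SERIES_ERR
        )
        scales = np.tile(np.array([0.3, 0.4, 0.15, 0.05]), (model.n_cells, 1))
        sig_scales = np.full((model.n_cond, 4), 0.3)
        t_scales = np.full((model.n_cond, 4), 0.1)
        r_scales = np.full((model.n_cond, 4), 0.3)
        accepted = np.zeros((model.n_cells, 4))
        sig_acc = np.zeros((model.n_cond, 4))
        iw_acc = np.zeros((model.n_cond, 4, 2))
        for it in range(n_iter):
            normals = rng.standard_normal((model.n_cells, 4))
            normals[:, ~update_mask] = 0.0
            log_unifs = np.log(rng.random((model.n_cells, 4)))
            log_unifs[:, ~update_mask] = np.inf  # never accept a fixed component
            mwg_sweep(
                model.rt, model.is_upper, model.sign, model.cell_ptr, model.cell_cond,
                theta, cur_ll, mu, sigma, scales, normals, log_unifs, model.min_rt,
                accepted, _SERIES_ERR,
            )
            _update_groups(model, theta, mu, sigma, sig_scales, sig_acc, rng)
            # interweaved non-centered moves keep group-level mixing alive
            # when the between-person SD is small
            for k in range(4):
                if not update_mask[k]:
                    continue
                for g, cells in model.group_cells[k].items():
                    conds = np.flatnonzero(model.group_of[:, k] == g)
                    mu_new, sig_new, a_t, a_r = group_interweave(
                        model.rt, model.is_upper, model.sign, model.cell_ptr, cells, k,
                        theta, cur_ll, mu[conds[0], k], sigma[conds[0], k],
                        model.m0[k], model.s0[k], spec.prior_sd_scale,
                        t_scales[g, k], r_scales[g, k],
                        rng.standard_normal(2), np.log(rng.random(2)),
                        model.min_rt, k == 3, _SERIES_ERR,
                    )
                    mu[conds, k] = mu_new
                    sigma[conds, k] = sig_new
                    iw_acc[g, k, 0] = a_t
                    iw_acc[g, k, 1] = a_r
            if it < spec.warmup:
                gamma = min(0.25, 2.0 / np.sqrt(it + 1.0))
                scales *= np.exp(gamma * (accepted - 0.44))
                sig_scales *= np.exp(gamma * (sig_acc - 0.44))
                t_scales *= np.exp(gamma * (iw_acc[:, :, 0] - 0.3))
                r_scales *= np.exp(gamma * (iw_acc[:, :, 1] - 0.3))
            else:
                j = it - spec.warmup
                mu_out[ch, j] = mu
                sig_out[ch, j] = sigma
                if th_out is not None:
                    th_out[ch, j] = theta
                th_mean += theta
                acc_tot += accepted
    th_mean /= spec.chains * n_keep

    # diagnostics on condition-level parameters only
    varying = [k for k in range(4) if update_mask[k]]
    stack = np.concatenate(
        [mu_out[..., varying].reshape(spec.chains, n_keep, -1),
         sig_out[..., varying].reshape(spec.chains, n_keep, -1)],
        axis=2,
    )
    rhat = az.rhat(az.convert_to_dataset(stack))["x"].to_numpy()
    ess = az.ess(az.convert_to_dataset(stack))["x"].to_numpy()
    rhat_max = float(np.nanmax(rhat))
    ess_min = float(np.nanmin(ess))
    converged = rhat_max <= spec.rhat_threshold and ess_min >= min(
        spec.ess_threshold, 0.5 * spec.chains * n_keep
    )
    if not converged:
        warnings.warn(
            f"MCMC diagnostics: max split R-hat {rhat_max:.3f}, min ESS {ess_min:.0f}; "
            "draws returned but treat condition-level summaries with caution.",
            stacklevel=2,
        )
    return FitResult(
        model=model, spec=spec, mu=mu_out, sigma=sig_out, theta=th_out,
        theta_mean=th_mean,
        accept_rates={"person": acc_tot / (spec.chains * n_keep)},
        rhat_max=rhat_max, ess_min=ess_min, converged=converged,
    )


def _marginal_mean_draws(result: FitResult, parameter: str, factor: str, level: str, probe_type: str):
    """Per-draw unweighted mean of the group means over cells matching
    (factor=level, probe_type), marginalizing the non-focal factors."""
    k = PARAM_NAMES.index(parameter)
    idx = [
        i
        for i, c in enumerate(result.conditions)
        if getattr(c, factor) == level and c.probe_type == probe_type
    ]
    if not idx:
        return None
    return result.mu_draws()[:, idx, k].mean(axis=1)


def condition_summaries(result: FitResult) -> pd.DataFrame:
    """Marginal posterior summaries per manipulated factor level and probe type.

    For each manipulation's matched parameter, the condition-level group means
    are averaged per draw over the cells of the non-focal factors (balanced
    design), then summarized — one row per (parameter, level, probe type).
    """
    probe_types = sorted({c.probe_type for c in result.conditions})
    rows = []
    for contrast, (param, factor, manip, base) in CONTRAST_DEFS.items():
        for level in (manip, base):
            for pt in probe_types:
                d = _marginal_mean_draws(result, param, factor, level, pt)
                if d is None:
                    continue
                rows.append(
                    {
                        "parameter": param,
                        "factor": factor,
                        "level": level,
                        "probe_type": pt,
                        **summarize_draws(d).to_dict(),
                    }
                )
    return pd.DataFrame(rows)


def contrasts(result: FitResult) -> list[ContrastResult]:
    """Manipulation-minus-baseline posterior contrasts per probe type.

    Each contrast is computed per posterior draw on the marginalized group
    means of its matched parameter (drift for study time, logit bias for
    change probability, log boundary for urgency), then summarized with the
    95% credible-interval rule.
    """
    probe_types = sorted({c.probe_type for c in result.conditions})
    out = []
    for contrast, (param, factor, manip, base) in CONTRAST_DEFS.items():
        for pt in probe_types:
            d_m = _marginal_mean_draws(result, param, factor, manip, pt)
            d_b = _marginal_mean_draws(result, param, factor, base, pt)
            if d_m is None or d_b is None:
                continue
            out.append(
                ContrastResult(
                    parameter=param,
                    contrast=contrast,
                    probe_type=pt,
                    summary=summarize_draws(d_m - d_b),
                )
            )
    return out
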