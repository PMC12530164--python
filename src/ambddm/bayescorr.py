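"""Bayesian Pearson correlation with a default-prior Bayes factor.

The population correlation rho gets a symmetric stretched-beta prior on
(-1, 1) (shape 1/width; width 1 gives a uniform prior — the default of
standard Bayesian-statistics software). The Bayes factor BF10 compares the
marginal likelihood of the correlation model against the point null rho = 0,
using the reduced likelihood of rho given the sample correlation r and sample
size n, and is computed by adaptive numerical integration. The posterior of
rho (same integrand, normalized) gives the central 95% credible interval.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import integrate, special

__all__ = [
    "CorrelationResult",
    "pearson_bf",
    "evidence_label",
    "corr_log_likelihood",
    "parameter_covariate_scan",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    bf10: float
    ci_low: float
    ci_high: float
    n: int
    evidence_label: str

    def to_dict(self) -> dict:
        return asdict(self)


def corr_log_likelihood(rho: float, n: int, r: float) -> float:
    """Log reduced likelihood of the population correlation rho given (n, r).

    Exact for bivariate-normal data up to a rho-free constant; depends on the
    data only through the sample correlation.
    """
    return float(
        ((n - 1) / 2) * np.log1p(-rho * rho)
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, (1.0 + rho * r) / 2.0))
    )


def _prior_pdf(rho, width: float):
    # stretched Beta(1/width, 1/width) on (-1, 1)
    a = 1.0 / width
    rho = np.asarray(rho, float)
    return ((1 - rho) ** (a - 1) * (1 + rho) ** (a - 1)) / (special.beta(a, a) * 2.0 ** (2 * a - 1))


def pearson_bf(x, y, prior_width: float = 1.0) -> CorrelationResult:
    """Sample Pearson r with BF10 and a 95% credible interval for rho.

    Requires n >= 4 finite observations per vector and nonzero variance in
    both. BF10 > 1 favors a nonzero population correlation (two-sided
    alternative); its reciprocal quantifies evidence for the null.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) > 1.0 - 1e-12:
        # exactly collinear data: the null has zero marginal likelihood
        return CorrelationResult(
            r=r, bf10=np.inf, ci_low=r, ci_high=r, n=n, evidence_label="extreme"
        )

    ll0 = corr_log_likelihood(0.0, n, r)

    def integrand(rho):
        return np.exp(corr_log_likelihood(rho, n, r) - ll0) * _prior_pdf(rho, prior_width)

    bf10, _ = integrate.quad(integrand, -1.0, 1.0, epsrel=1e-6, limit=400)

    grid = np.linspace(-0.9999, 0.9999, 8001)
    post = np.array([integrand(g) for g in grid])
    cdf = integrate.cumulative_trapezoid(post, grid, initial=0.0)
    cdf /= cdf[-1]
    ci_low, ci_high = np.interp([0.025, 0.975], cdf, grid)
    return CorrelationResult(
        r=r, bf10=float(bf10), ci_low=float(ci_low), ci_high=float(ci_high),
        n=n, evidence_label=evidence_label(float(bf10)),
    )


def evidence_label(bf10: float) -> str:
    """Evidence category for BF10 on the conventional bands.

    1-3 anecdotal, 3-10 moderate, 10-30 strong, 30-100 very strong, >100
    extreme — for the alternative when BF10 >= 1, with the mirrored
    ``*_null`` labels via the reciprocal when BF10 < 1.
    """
    if not (np.isfinite(bf10) and bf10 > 0):
        raise ValueError(f"bf10 must be a positive number, got {bf10}")
    side_null = bf10 < 1.0
    b = 1.0 / bf10 if side_null else bf10
    for bound, name in ((3, "anecdotal"), (10, "moderate"), (30, "strong"), (100, "very strong")):
        if b < bound:
            label = name
            break
    else:
        label = "extreme"
    return f"{label}_null" if side_null else label


def parameter_covariate_scan(
    person_params: pd.DataFrame,
    covariates: pd.DataFrame,
    groupings: dict | None = None,
    prior_width: float = 1.0,
) -> pd.DataFrame:
    """Correlate person-level parameters with covariates, per grouping.

    ``person_params`` is indexed by participant with one column per
    (parameter, grouping) — as produced by aggregating posterior means over
    the grouping's conditions — or per parameter when ``groupings`` is None.
    ``covariates`` is indexed by participant (e.g. an ``age`` column). Returns
    one row per (parameter, grouping, covariate); degenerate cells surface
    their error message and the scan continues.
    """
    rows = []
    for col in person_params.columns:
        if isinstance(col, tuple):
            parameter, grouping = col
        else:
            parameter, grouping = col, "overall"
        for cov in covariates.columns:
            joined = pd.concat([person_params[col], covariates[cov]], axis=1, join="inner").dropna()
            base = {"parameter": parameter, "grouping": grouping, "covariate": cov}
            try:
                res = pearson_bf(joined.iloc[:, 0], joined.iloc[:, 1], prior_width)
                rows.append({**base, **res.to_dict(), "error": None})
            except ValueError as e:
                rows.append({**base, "error": str(e)})
    return pd.DataFrame(rows)
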