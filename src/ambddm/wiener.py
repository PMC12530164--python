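"""Two-boundary Wiener diffusion first-passage numerics.

The drift diffusion model treats a two-choice decision as a Wiener process
with drift that starts at ``boundary * bias`` and terminates when it first
hits 0 (lower boundary) or ``boundary`` (upper boundary). This module provides
the exact joint density of (response time, absorbed boundary), the closed-form
absorbing probability, and an exact (inverse-CDF) trial sampler. The diffusion
coefficient is fixed at 1 with time in seconds — the standard identifiability
convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import _SERIES_ERR, fpt_lower_logpdf, fpt_lower_pdf_grid

__all__ = ["DDMParams", "wfpt_logdensity", "prob_upper", "sample_trials", "moments"]

UPPER = "upper"
LOWER = "lower"


@dataclass(frozen=True)
class DDMParams:
    """Diffusion parameters for one person-condition cell.

    drift
        Mean evidence accumulation rate (evidence units / s); positive values
        drive the process toward the upper boundary.
    boundary
        Boundary separation (> 0).
    bias
        Relative start point in (0, 1); start = boundary * bias.
    ndt
        Nondecision time in seconds (>= 0).
    """

    drift: float
    boundary: float
    bias: float
    ndt: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.drift):
            raise ValueError("drift must be finite")
        if not (self.boundary > 0 and np.isfinite(self.boundary)):
            raise ValueError(f"boundary must be positive, got {self.boundary}")
        if not 0.0 < self.bias < 1.0:
            raise ValueError(f"bias must lie strictly in (0, 1), got {self.bias}")
        if not (self.ndt >= 0 and np.isfinite(self.ndt)):
            raise ValueError(f"ndt must be nonnegative, got {self.ndt}")


def wfpt_logdensity(t, choice: str, params: DDMParams) -> np.ndarray | float:
    """Log joint density of (first-passage time = t, absorbed boundary = choice).

    ``t`` may be a scalar or array of RTs in seconds. Times at or before the
    nondecision time carry zero mass and return ``-inf`` (data cleaning is the
    preprocessing layer's job, not the likelihood's). The lower-boundary
    density is the upper-boundary one under the reflection
    (drift -> -drift, bias -> 1 - bias).
    """
    if choice not in (UPPER, LOWER):
        raise ValueError(f"choice must be '{UPPER}' or '{LOWER}', got {choice!r}")
    if choice == UPPER:
        v, w = -params.drift, 1.0 - params.bias
    else:
        v, w = params.drift, params.bias
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty(t_arr.shape)
    for i, ti in enumerate(t_arr):
        out[i] = fpt_lower_logpdf(ti - params.ndt, v, params.boundary, w, _SERIES_ERR)
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def prob_upper(params: DDMParams) -> float:
    """Probability that the process is absorbed at the upper boundary.

    Closed form (1 - exp(-2 v a w)) / (1 - exp(-2 v a)) for drift v != 0,
    and the relative start point for a driftless process.
    """
    v, a, w = params.drift, params.boundary, params.bias
    if abs(v * a) < 1e-10:
        return w
    return float(np.expm1(-2.0 * v * a * w) / np.expm1(-2.0 * v * a))


def _decision_time_grid(params: DDMParams, n_grid: int = 8192) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grid of decision times with per-boundary densities covering ~all mass."""
    v, a, w = params.drift, params.boundary, params.bias
    t_max = 4.0 * a * a  # starting guess; extended until the tail is negligible
    while t_max < 512.0:
        grid = np.linspace(1e-6, t_max, n_grid)
        f_lo = fpt_lower_pdf_grid(grid, v, a, w, _SERIES_ERR)
        f_up = fpt_lower_pdf_grid(grid, -v, a, 1.0 - w, _SERIES_ERR)
        mass = np.trapezoid(f_lo + f_up, grid)
        if mass > 1.0 - 1e-9 or (f_lo[-1] + f_up[-1]) * t_max < 1e-10:
            return grid, f_up, f_lo
        t_max *= 2.0
    return grid, f_up, f_lo


def moments(params: DDMParams) -> dict:
    """Mean and variance of the RT distribution, overall and per boundary.

    Computed by quadrature of the exact density on the sampler's grid; keys
    ``mean_rt``, ``var_rt``, ``mean_rt_upper``, ``mean_rt_lower`` (seconds).
    """
    grid, f_up, f_lo = _decision_time_grid(params)
    p_up = prob_upper(params)
    out = {}
    m_up = np.trapezoid(grid * f_up, grid) / max(p_up, 1e-300)
    m_lo = np.trapezoid(grid * f_lo, grid) / max(1 - p_up, 1e-300)
    total = f_up + f_lo
    m = np.trapezoid(grid * total, grid)
    m2 = np.trapezoid(grid**2 * total, grid)
    out["mean_rt"] = float(params.ndt + m)
    out["var_rt"] = float(m2 - m * m)
    out["mean_rt_upper"] = float(params.ndt + m_up)
    out["mean_rt_lower"] = float(params.ndt + m_lo)
    return out


def sample_trials(params: DDMParams, n: int, seed) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` iid (choice, RT) pairs from the exact first-passage law.

    Sampling is by inverse CDF on a dense quadrature grid of the exact
    density, conditional on the boundary chosen with :func:`prob_upper`.
    Returns ``(choice_upper, rt)`` where ``choice_upper`` is a boolean array
    and ``rt`` is in seconds, always strictly greater than ``ndt``.

    ``seed`` may be an int or a :class:`numpy.random.Generator`; equal seeds
    give identical output.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    choice_upper = np.empty(0, dtype=bool)
    rt = np.empty(0)
    if n == 0:
        return choice_upper, rt

    p_up = prob_upper(params)
    choice_upper = rng.random(n) < p_up
    grid, f_up, f_lo = _decision_time_grid(params)
    rt = np.empty(n)
    for is_up, dens in ((True, f_up), (False, f_lo)):
        idx = np.flatnonzero(choice_upper == is_up)
        if idx.size == 0:
            continue
        cdf = np.concatenate(([0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))))
        cdf /= cdf[-1]
        u = rng.random(idx.size)
        rt[idx] = params.ndt + np.interp(u, cdf, grid)
    return choice_upper, rt
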