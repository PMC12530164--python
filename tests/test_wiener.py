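"""Wiener first-passage core: density exactness, closed forms, sampler law."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from numba import njit
from scipy import integrate, stats

from ambddm import DDMParams, prob_upper, sample_trials, wfpt_logdensity
from ambddm.wiener import moments

# joint density of (upper hit, t=0.8) for drift=1, boundary=1, bias=.5, ndt=.3,
# frozen from a >=1000-term large-time series evaluation, cross-checked against
# a 200k-path Euler-Maruyama histogram (dt=1e-4) before trusting the fast path
DENSITY_UPPER_T08 = 0.3420934880344572


@pytest.mark.parametrize(
    "kwargs",
    [
        {"drift": 0.0, "boundary": -1.0, "bias": 0.5},
        {"drift": 0.0, "boundary": 0.0, "bias": 0.5},
        {"drift": 0.0, "boundary": 1.0, "bias": 0.0},
        {"drift": 0.0, "boundary": 1.0, "bias": 1.0},
        {"drift": 0.0, "boundary": 1.0, "bias": 0.5, "ndt": -0.1},
        {"drift": np.inf, "boundary": 1.0, "bias": 0.5},
    ],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValueError):
        DDMParams(**kwargs)


@pytest.mark.parametrize("choice", ["upper", "lower"])
@pytest.mark.parametrize("t", [0.3, 0.29, 0.0])
def test_no_mass_at_or_before_ndt(choice, t):
    p = DDMParams(1.2, 1.5, 0.4, ndt=0.3)
    assert wfpt_logdensity(t, choice, p) == -np.inf


def test_driftless_symmetric_process_has_equal_choice_densities():
    p = DDMParams(0.0, 1.0, 0.5)
    ts = np.linspace(0.05, 4.0, 40)
    np.testing.assert_allclose(
        wfpt_logdensity(ts, "upper", p), wfpt_logdensity(ts, "lower", p), rtol=1e-12
    )


def test_density_matches_series_and_simulation_oracle():
    p = DDMParams(1.0, 1.0, 0.5, ndt=0.3)
    assert wfpt_logdensity(0.8, "upper", p) == pytest.approx(np.log(DENSITY_UPPER_T08), abs=1e-6)


@pytest.mark.parametrize(
    "drift,boundary,bias,ndt",
    [(1.0, 1.0, 0.5, 0.3), (-2.0, 2.0, 0.3, 0.1), (0.5, 0.8, 0.7, 0.0)],
)
def test_reflection_symmetry_exact(drift, boundary, bias, ndt):
    ts = np.linspace(ndt + 0.01, ndt + 3.0, 25)
    up = wfpt_logdensity(ts, "upper", DDMParams(drift, boundary, bias, ndt))
    lo = wfpt_logdensity(ts, "lower", DDMParams(-drift, boundary, 1 - bias, ndt))
    np.testing.assert_array_equal(up, lo)


def _quad_choice_mass(p, choice):
    return integrate.quad(
        lambda t: np.exp(wfpt_logdensity(t, choice, p)), p.ndt, np.inf, limit=300
    )[0]


@pytest.mark.parametrize("drift", [-3.0, -1.0, 0.0, 1.0, 3.0])
@pytest.mark.parametrize("boundary,bias", [(0.5, 0.1), (1.5, 0.5), (3.0, 0.9)])
def test_density_normalizes_and_matches_closed_form_choice_probability(drift, boundary, bias):
    p = DDMParams(drift, boundary, bias)
    m_up = _quad_choice_mass(p, "upper")
    m_lo = _quad_choice_mass(p, "lower")
    assert m_up + m_lo == pytest.approx(1.0, abs=1e-4)
    assert m_up == pytest.approx(prob_upper(p), abs=1e-4)


def test_prob_upper_trivial_and_closed_form_values():
    assert prob_upper(DDMParams(0.0, 1.0, 0.5)) == pytest.approx(0.5)
    assert prob_upper(DDMParams(0.0, 2.0, 0.8)) == pytest.approx(0.8)
    # (1 - e^-1) / (1 - e^-2), verified against a 1e6-path simulation during development
    assert prob_upper(DDMParams(1.0, 1.0, 0.5)) == pytest.approx(0.7310585786, abs=1e-9)


@given(
    drift=st.floats(-3, 3),
    ddrift=st.floats(0.01, 1.0),
    boundary=st.floats(0.5, 3),
    bias=st.floats(0.15, 0.85),
    dbias=st.floats(0.01, 0.1),
)
@settings(max_examples=60, deadline=None)
def test_prob_upper_strictly_increasing_in_drift_and_bias(drift, ddrift, boundary, bias, dbias):
    base = prob_upper(DDMParams(drift, boundary, bias))
    assert prob_upper(DDMParams(drift + ddrift, boundary, bias)) > base
    assert prob_upper(DDMParams(drift, boundary, bias + dbias)) > base
    assert 0.0 < base < 1.0


def test_moments_match_closed_forms():
    # driftless symmetric start: E[decision time] = boundary^2 / 4
    m = moments(DDMParams(0.0, 2.0, 0.5, ndt=0.2))
    assert m["mean_rt"] == pytest.approx(0.2 + 1.0, rel=1e-4)
    # symmetric start with drift: E[T] = (a / 2v) tanh(a v / 2)
    v, a = 1.0, 1.5
    m2 = moments(DDMParams(v, a, 0.5))
    assert m2["mean_rt"] == pytest.approx(a / (2 * v) * np.tanh(a * v / 2), rel=1e-4)
    assert m2["var_rt"] > 0
    # conditional means combine to the overall mean
    p = prob_upper(DDMParams(v, a, 0.5))
    combined = p * m2["mean_rt_upper"] + (1 - p) * m2["mean_rt_lower"]
    assert combined == pytest.approx(m2["mean_rt"], rel=1e-4)


def test_sampler_empty_and_seed_contract():
    p = DDMParams(1.0, 1.0, 0.5, ndt=0.3)
    ch, rt = sample_trials(p, 0, seed=1)
    assert ch.size == 0 and rt.size == 0
    a = sample_trials(p, 50, seed=11)
    b = sample_trials(p, 50, seed=11)
    np.testing.assert_array_equal(a[0], b[0])
    np.testing.assert_array_equal(a[1], b[1])
    assert (a[1] > p.ndt).all()


def test_sampler_choice_fraction_and_ks_against_integrated_cdf():
    p = DDMParams(1.0, 1.0, 0.5, ndt=0.3)
    n = 100_000
    ch, rt = sample_trials(p, n, seed=3)
    pu = prob_upper(p)
    se = np.sqrt(pu * (1 - pu) / n)
    assert abs(ch.mean() - pu) < 3 * se

    from ambddm.wiener import _decision_time_grid

    grid, f_up, f_lo = _decision_time_grid(p)
    for is_up, dens, mass in ((True, f_up, pu), (False, f_lo, 1 - pu)):
        cdf = np.concatenate([[0.0], integrate.cumulative_trapezoid(dens, grid)])
        cdf /= cdf[-1]
        x = np.sort(rt[ch == is_up] - p.ndt)
        emp = np.arange(1, x.size + 1) / x.size
        ks = np.abs(np.interp(x, grid, cdf) - emp).max()
        assert ks < 0.01


@njit
def _euler_maruyama_rts(drift, boundary, start, ndt, n, dt, seed):
    """Independent discretized-path oracle (test-only, never the production
    sampler). Boundaries are pulled in by the Broadie-Glasserman continuity
    correction 0.5826*sqrt(dt) to offset the O(sqrt(dt)) overshoot bias."""
    np.random.seed(seed)
    c = 0.5826 * np.sqrt(dt)
    lo, hi = c, boundary - c
    rts = np.empty(n)
    ups = np.empty(n, dtype=np.bool_)
    sq = np.sqrt(dt)
    for i in range(n):
        x = start
        t = 0.0
        while lo < x < hi:
            x += drift * dt + sq * np.random.standard_normal()
            t += dt
        rts[i] = ndt + t
        ups[i] = x >= hi
    return ups, rts


def test_sampler_agrees_with_euler_maruyama_oracle():
    p = DDMParams(1.0, 1.0, 0.5, ndt=0.3)
    n = 20_000
    ch, rt = sample_trials(p, n, seed=5)
    ups, rts = _euler_maruyama_rts(p.drift, p.boundary, p.boundary * p.bias, p.ndt, n, 1e-4, 12345)
    assert abs(ups.mean() - ch.mean()) < 4 * np.sqrt(0.25 / n)
    for sel in (True, False):
        ks = stats.ks_2samp(rt[ch == sel], rts[ups == sel])
        assert ks.pvalue > 0.01  # same law up to residual discretization error
        assert ks.statistic < 0.03
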