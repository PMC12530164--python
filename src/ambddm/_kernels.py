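"""Numba kernels for the Wiener first-passage-time density and MCMC sweeps.

Everything here operates on raw floats/arrays; user-facing validation and
parameter containers live in :mod:`ambddm.wiener` and :mod:`ambddm.model`.
The density follows the dual small-time / large-time series representation,
choosing per evaluation whichever needs fewer terms at a fixed absolute
truncation error.
"""

import numpy as np
from numba import njit

_SERIES_ERR = 1e-7  # absolute truncation error of the normalized-time density


@njit(cache=True)
def fpt_lower_logpdf(t_dec, drift, boundary, bias, err):
    """Log joint density of (first passage at *lower* boundary, decision time t_dec).

    Diffusion coefficient is fixed at 1; time in seconds. Returns -inf for
    t_dec <= 0 (no decision mass at or before the nondecision time).
    """
    if t_dec <= 0.0:
        return -np.inf
    a2 = boundary * boundary
    u = t_dec / a2  # normalized time
    if u < 1e-9:  # negligible mass this close to the nondecision time
        return -np.inf
    w = bias

    # term counts needed at error `err` (normalized-time density scale)
    if 2.0 * np.sqrt(2.0 * np.pi * u) * err < 1.0:
        ks = 2.0 + np.sqrt(-2.0 * u * np.log(2.0 * err * np.sqrt(2.0 * np.pi * u)))
        if ks < np.sqrt(u) + 1.0:
            ks = np.sqrt(u) + 1.0
    else:
        ks = 2.0
    if np.pi * u * err < 1.0:
        kl = np.sqrt(-2.0 * np.log(np.pi * u * err) / (np.pi * np.pi * u))
        if kl < 1.0 / (np.pi * np.sqrt(u)):
            kl = 1.0 / (np.pi * np.sqrt(u))
    else:
        kl = 1.0 / (np.pi * np.sqrt(u))

    if ks < kl:  # small-time representation
        K = int(np.ceil(ks))
        s = 0.0
        for k in range(-K, K + 1):
            z = w + 2.0 * k
            s += z * np.exp(-z * z / (2.0 * u))
        f_u = s / np.sqrt(2.0 * np.pi * u * u * u)
    else:  # large-time representation
        K = int(np.ceil(kl))
        s = 0.0
        for k in range(1, K + 1):
            s += k * np.exp(-k * k * np.pi * np.pi * u / 2.0) * np.sin(k * np.pi * w)
        f_u = np.pi * s
    if f_u <= 0.0:  # truncation round-off deep in a tail
        f_u = 1e-300
    return (
        np.log(f_u)
        - np.log(a2)
        - drift * boundary * w
        - drift * drift * t_dec / 2.0
    )


@njit(cache=True)
def wfpt_logpdf(t, upper, drift, boundary, bias, ndt, err):
    """Log density of (RT = t, absorbed at upper/lower boundary).

    The upper-boundary density is the lower-boundary one under the reflection
    (drift -> -drift, bias -> 1-bias).
    """
    if upper:
        return fpt_lower_logpdf(t - ndt, -drift, boundary, 1.0 - bias, err)
    return fpt_lower_logpdf(t - ndt, drift, boundary, bias, err)


@njit(cache=True)
def fpt_lower_pdf_grid(t_dec, drift, boundary, bias, err):
    out = np.empty(t_dec.size)
    for i in range(t_dec.size):
        out[i] = np.exp(fpt_lower_logpdf(t_dec[i], drift, boundary, bias, err))
    return out


@njit(cache=True)
def cell_loglik(rt, upper, sign, j0, j1, drift, boundary, bias, ndt, err):
    """Summed trial log likelihood for one person-condition cell.

    `sign` carries the stimulus-coding drift sign per trial (+1 on *different*
    trials, -1 on *same* trials); `drift` is the condition-level magnitude.
    """
    total = 0.0
    for j in range(j0, j1):
        v = drift * sign[j]
        if upper[j]:
            lp = fpt_lower_logpdf(rt[j] - ndt, -v, boundary, 1.0 - bias, err)
        else:
            lp = fpt_lower_logpdf(rt[j] - ndt, v, boundary, bias, err)
        total += lp
        if total == -np.inf:
            break
    return total


@njit(cache=True)
def _cell_loglik_theta(rt, upper, sign, j0, j1, th, err):
    # reject absurd proposals before exp/logistic over- or underflow
    if abs(th[0]) > 1e3 or abs(th[1]) > 500.0 or abs(th[2]) > 20.0:
        return -np.inf
    drift = th[0]
    bias = 1.0 / (1.0 + np.exp(-th[1]))
    boundary = np.exp(th[2])
    return cell_loglik(rt, upper, sign, j0, j1, drift, boundary, bias, th[3], err)


@njit(cache=True)
def init_cell_logliks(rt, upper, sign, cell_ptr, theta, err):
    n_cells = theta.shape[0]
    out = np.empty(n_cells)
    for c in range(n_cells):
        out[c] = _cell_loglik_theta(
            rt, upper, sign, cell_ptr[c], cell_ptr[c + 1], theta[c], err
        )
    return out


@njit(cache=True)
def group_interweave(
    rt,
    upper,
    sign,
    cell_ptr,
    cells,
    k,
    theta,
    cur_ll,
    mu_val,
    sigma_val,
    m0k,
    s0k,
    sd_scale,
    trans_scale,
    rescale_scale,
    normals,
    log_unifs,
    min_rt,
    is_ndt,
    err,
):
    """Interweaving (non-centered) moves for one group-level (mean, SD) pair.

    Move 1 translates the group mean and all its person-condition values
    together; move 2 rescales person deviations jointly with the group SD.
    Both target the joint posterior directly through the trial likelihood, so
    they keep mixing alive when the group SD is near zero (the hierarchical
    funnel, where centered Gibbs updates stall). Mutates theta and cur_ll on
    acceptance; returns (mu, sigma, accept_translate, accept_rescale).
    """
    n = cells.size
    acc_t = 0.0
    acc_r = 0.0

    # -- translation: mu' = mu + d, theta' = theta + d ----------------------
    d = trans_scale * normals[0]
    ok = True
    if is_ndt:
        if mu_val + d < 0.0:
            ok = False
        else:
            for i in range(n):
                c = cells[i]
                v = theta[c, k] + d
                if v < 0.0 or v >= min_rt[c]:
                    ok = False
                    break
    if ok:
        dll = 0.0
        new_ll = np.empty(n)
        for i in range(n):
            c = cells[i]
            old = theta[c, k]
            theta[c, k] = old + d
            new_ll[i] = _cell_loglik_theta(rt, upper, sign, cell_ptr[c], cell_ptr[c + 1], theta[c], err)
            theta[c, k] = old
            dll += new_ll[i] - cur_ll[c]
            if dll == -np.inf:
                break
        dprior = 0.5 * ((mu_val - m0k) / s0k) ** 2 - 0.5 * ((mu_val + d - m0k) / s0k) ** 2
        if log_unifs[0] < dll + dprior:
            for i in range(n):
                c = cells[i]
                theta[c, k] += d
                cur_ll[c] = new_ll[i]
            mu_val = mu_val + d
            acc_t = 1.0

    # -- rescale: sigma' = sigma * e^eps, deviations scaled along -----------
    ls_old = np.log(sigma_val)
    ls_new = ls_old + rescale_scale * normals[1]
    sig_new = np.exp(ls_new)
    if sig_new > 1e-4 and sig_new < 1e3:
        ratio = sig_new / sigma_val
        ok = True
        if is_ndt:
            for i in range(n):
                c = cells[i]
                v = mu_val + ratio * (theta[c, k] - mu_val)
                if v < 0.0 or v >= min_rt[c]:
                    ok = False
                    break
        if ok:
            dll = 0.0
            new_ll = np.empty(n)
            new_th = np.empty(n)
            for i in range(n):
                c = cells[i]
                old = theta[c, k]
                new_th[i] = mu_val + ratio * (old - mu_val)
                theta[c, k] = new_th[i]
                new_ll[i] = _cell_loglik_theta(rt, upper, sign, cell_ptr[c], cell_ptr[c + 1], theta[c], err)
                theta[c, k] = old
                dll += new_ll[i] - cur_ll[c]
                if dll == -np.inf:
                    break
            # prior(theta|mu,sigma) change cancels against the Jacobian of the
            # deterministic rescale; only the SD prior and log-scale Jacobian remain
            dprior = (sigma_val**2 - sig_new**2) / (2.0 * sd_scale**2) + (ls_new - ls_old)
            if log_unifs[1] < dll + dprior:
                for i in range(n):
                    c = cells[i]
                    theta[c, k] = new_th[i]
                    cur_ll[c] = new_ll[i]
                sigma_val = sig_new
                acc_r = 1.0
    return mu_val, sigma_val, acc_t, acc_r


@njit(cache=True)
def mwg_sweep(
    rt,
    upper,
    sign,
    cell_ptr,
    cond_idx,
    theta,
    cur_ll,
    mu,
    sigma,
    scales,
    normals,
    log_unifs,
    min_rt,
    accepted,
    err,
):
    """One componentwise Metropolis-within-Gibbs sweep over person-condition cells.

    theta[c] = (drift, logit bias, log boundary, ndt) for cell c; the conditional
    prior of each component is Normal(mu[cond, k], sigma[cond, k]). Randomness is
    passed in, so the sweep is deterministic given its inputs. Updates theta,
    cur_ll and accepted in place.
    """
    n_cells = theta.shape[0]
    for c in range(n_cells):
        j0 = cell_ptr[c]
        j1 = cell_ptr[c + 1]
        ci = cond_idx[c]
        for k in range(4):
            old = theta[c, k]
            new = old + scales[c, k] * normals[c, k]
            if k == 3 and (new < 0.0 or new >= min_rt[c]):
                accepted[c, k] = 0.0
                continue
            s = sigma[ci, k]
            m = mu[ci, k]
            dlp = 0.5 * ((old - m) / s) ** 2 - 0.5 * ((new - m) / s) ** 2
            theta[c, k] = new
            new_ll = _cell_loglik_theta(rt, upper, sign, j0, j1, theta[c], err)
            if log_unifs[c, k] < dlp + new_ll - cur_ll[c]:
                cur_ll[c] = new_ll
                accepted[c, k] = 1.0
            else:
                theta[c, k] = old
                accepted[c, k] = 0.0
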