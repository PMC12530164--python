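"""Posterior predictive checks via correct/error RT quantiles per condition.

For each posterior draw used, a full dataset is simulated under the observed
design — same persons, conditions, trial counts and trial truths — then passed
through the same deadline censoring and RT-bound retention as the observed
data. Observed RT quantiles (split by response correctness, per condition)
are compared with the across-simulation median and a central 95% predictive
band; the coverage score is the fraction of observed quantile points falling
inside their bands.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import FitResult, PARAM_NAMES
from .preprocess import RT_MIN_MS, RT_MAX_MS
from .wiener import DDMParams, sample_trials

__all__ = ["posterior_predictive", "rt_quantile_check", "plot_quantile_check", "DEFAULT_LEVELS"]

DEFAULT_LEVELS = (0.1, 0.3, 0.5, 0.7, 0.9)


def posterior_predictive(
    result: FitResult,
    design: pd.DataFrame,
    n_sim: int = 6000,
    seed: int = 0,
    apply_retention: bool = True,
) -> list[pd.DataFrame]:
    """Simulate ``n_sim`` datasets from the fitted posterior under ``design``.

    ``design`` is the retained trial table the model was fit to (or any table
    with the same columns): per-cell trial counts and truths are preserved
    exactly. Posterior draws are sampled uniformly; if ``n_sim`` exceeds the
    available draws they are resampled with replacement. Each simulated
    dataset is censored at the design's response deadline and, when
    ``apply_retention``, filtered by the same RT bounds as observed data.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    model = result.model
    if result.theta is None:
        raise ValueError("fit was run without stored person draws")
    rng = np.random.default_rng(seed)
    th = result.theta.reshape(-1, model.n_cells, 4)
    n_avail = th.shape[0]
    draw_idx = (
        rng.choice(n_avail, size=n_sim, replace=n_sim > n_avail)
        if n_sim != n_avail
        else np.arange(n_sim)
    )

    # per-cell design info, in the model's cell order
    cells = []
    for c in range(model.n_cells):
        sl = slice(model.cell_ptr[c], model.cell_ptr[c + 1])
        cond = model.conditions[model.cell_cond[c]]
        cells.append((model.sign[sl].copy(), cond))

    sims = []
    for d in draw_idx:
        rows_rt, rows_ok, rows_cond, rows_truth = [], [], [], []
        for (sign, cond), theta in zip(cells, th[d]):
            params = DDMParams(
                drift=float(theta[0]),
                boundary=float(np.exp(theta[2])),
                bias=float(1.0 / (1.0 + np.exp(-theta[1]))),
                ndt=float(theta[3]),
            )
            rt_s = np.empty(sign.size)
            up = np.empty(sign.size, dtype=bool)
            for s_val in (1.0, -1.0):
                idx = np.flatnonzero(sign == s_val)
                if idx.size == 0:
                    continue
                p = DDMParams(params.drift * s_val, params.boundary, params.bias, params.ndt)
                up[idx], rt_s[idx] = sample_trials(p, idx.size, rng)
            rt_ms = rt_s * 1000.0
            keep = rt_ms <= cond.deadline_ms
            if apply_retention:
                keep &= (rt_ms >= RT_MIN_MS) & (rt_ms <= RT_MAX_MS)
            rows_rt.append(rt_ms[keep])
            rows_ok.append((up[keep] == (sign[keep] > 0)))
            rows_cond.append(np.full(keep.sum(), cond.version_index))
            rows_truth.append(np.where(sign[keep] > 0, "different", "same"))
        sims.append(
            pd.DataFrame(
                {
                    "version_index": np.concatenate(rows_cond),
                    "truth": np.concatenate(rows_truth),
                    "correct": np.concatenate(rows_ok),
                    "rt_ms": np.concatenate(rows_rt),
                }
            )
        )
    return sims


def _observed_frame(observed: pd.DataFrame) -> pd.DataFrame:
    df = observed.copy()
    df["correct"] = df["response"] == df["truth"]
    return df[["version_index", "correct", "rt_ms"]]


def rt_quantile_check(
    observed: pd.DataFrame,
    simulated: list[pd.DataFrame],
    levels=DEFAULT_LEVELS,
    min_trials: int = 5,
) -> tuple[pd.DataFrame, float]:
    """Observed vs posterior-predictive RT quantiles by condition and correctness.

    Returns ``(table, coverage)``. The table holds, per (condition,
    correctness, level): the observed quantile, the across-simulation median
    and central 95% predictive band, and whether the observed value falls
    inside the band. Cells with fewer than ``min_trials`` observed trials are
    flagged as skipped (their quantiles are unstable) and do not count toward
    the coverage score. Quantiles use linear interpolation of order statistics.
    """
    if not simulated:
        raise ValueError("need at least one simulated dataset")
    levels = np.asarray(levels, float)
    obs = _observed_frame(observed)

    rows = []
    for (vi, corr), g in obs.groupby(["version_index", "correct"]):
        q_obs = np.quantile(g["rt_ms"], levels) if len(g) >= min_trials else None
        sim_q = []
        for sim in simulated:
            s = sim[(sim["version_index"] == vi) & (sim["correct"] == corr)]["rt_ms"]
            sim_q.append(np.quantile(s, levels) if len(s) >= 2 else np.full(levels.size, np.nan))
        sim_q = np.asarray(sim_q)
        with np.errstate(all="ignore"):
            pred_med = np.nanmedian(sim_q, axis=0)
            lo, hi = np.nanpercentile(sim_q, [2.5, 97.5], axis=0)
        for i, lev in enumerate(levels):
            skipped = q_obs is None or np.isnan(pred_med[i])
            rows.append(
                {
                    "version_index": vi,
                    "correctness": "correct" if corr else "error",
                    "level": lev,
                    "observed_s": None if q_obs is None else q_obs[i] / 1000.0,
                    "predicted_s": pred_med[i] / 1000.0,
                    "band_low_s": lo[i] / 1000.0,
                    "band_high_s": hi[i] / 1000.0,
                    "skipped": skipped,
                    "inside": (
                        bool(lo[i] <= q_obs[i] <= hi[i]) if not skipped else None
                    ),
                }
            )
    table = pd.DataFrame(rows)
    scored = table[~table["skipped"]]
    coverage = float(scored["inside"].mean()) if len(scored) else float("nan")
    return table, coverage


def plot_quantile_check(table: pd.DataFrame, path=None):
    """Observed (circles: filled=correct, open=error) vs predicted quantile bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    versions = sorted(table["version_index"].unique())
    ncol = min(4, len(versions))
    nrow = int(np.ceil(len(versions) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.8 * nrow), squeeze=False)
    for ax, vi in zip(axes.ravel(), versions):
        sub = table[table["version_index"] == vi]
        for corr, filled in (("correct", True), ("error", False)):
            s = sub[(sub["correctness"] == corr) & (~sub["skipped"])]
            if s.empty:
                continue
            ax.errorbar(
                s["level"], s["predicted_s"],
                yerr=[s["predicted_s"] - s["band_low_s"], s["band_high_s"] - s["predicted_s"]],
                fmt="_", color="0.6", capsize=2,
            )
            ax.scatter(
                s["level"], s["observed_s"],
                facecolors="k" if filled else "none", edgecolors="k", zorder=3, s=18,
            )
        ax.set_title(f"version {vi}", fontsize=9)
        ax.set_xlabel("quantile")
        ax.set_ylabel("RT (s)")
    for ax in axes.ravel()[len(versions):]:
        ax.axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
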