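"""Optimal-time estimation from data: bootstrap CIs, distribution-shift
optima, and risk-attitude classification.

Three inferential tools sit on top of the decision model:

* :func:`bootstrap_ci` — for each motor SD sigma on a grid, the optimal plan
  T*(sigma) and a percentile 95% CI of the *mean of a 100-trial session*
  executed exactly at (T*, sigma). A participant whose observed mean falls
  outside the CI at their sigma cannot be explained as a risk-neutral
  expected-gain maximizer.
* :func:`empirical_optimum` — a model-free check: translate the observed
  sample of response times along the time axis until its total gain is
  maximal; the shifted mean is the distribution's own optimal mean time.
* :func:`classify_strategy` — risk_seeking / risk_neutral / risk_averse by
  which side of the CI the observed mean falls on, with "seeking" meaning
  closer than optimal to the zero-gain boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decision import optimal_plan
from .gains import GainFunction

RISK_CONDITIONS = ("risk_after", "risk_before")


@dataclass(frozen=True)
class EmpiricalOptimum:
    """Distribution-shift optimum of one observed session."""

    observed_mean_time: float  # ms
    optimal_shift: float  # ms, s* maximizing total gain of shifted sample
    optimal_mean_time: float  # ms, observed mean + s*
    observed_total_gain: float  # points, at shift 0
    optimal_total_gain: float  # points, at s*


@dataclass(frozen=True)
class RiskClassification:
    label: str  # risk_neutral | risk_seeking | risk_averse
    observed_mean: float
    ci: tuple[float, float]
    condition_label: str


def _percentile_ci(means: np.ndarray) -> tuple[float, float]:
    """2.5% and 97.5% points of the sorted replicate means."""
    lo, hi = np.quantile(means, [0.025, 0.975])
    return float(lo), float(hi)


def bootstrap_ci_at_sigma(
    g: GainFunction,
    sigma: float,
    n_replicates: int = 3000,
    n_trials: int = 100,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """(T*, lower, upper) for one sigma: simulate ``n_replicates`` sessions
    of ``n_trials`` Gaussian trials at (T*(sigma), sigma) and take the
    percentile CI of the session means."""
    if n_replicates < 1 or n_trials < 1:
        raise ValueError("n_replicates and n_trials must be >= 1")
    t_opt = optimal_plan(g, sigma).optimal_time
    if sigma == 0.0:
        return t_opt, t_opt, t_opt
    if rng is None:
        rng = np.random.default_rng(seed)
    means = rng.normal(t_opt, sigma, size=(n_replicates, n_trials)).mean(axis=1)
    lo, hi = _percentile_ci(means)
    return t_opt, lo, hi


def bootstrap_ci(
    g: GainFunction,
    sigma_grid_max: float = 400.0,
    sigma_step: float = 1.0,
    n_replicates: int = 3000,
    n_trials: int = 100,
    seed: int | None = None,
    sigma_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Bootstrap CI of the optimal mean response time over a sigma grid.

    Returns a frame with columns ``sigma, t_opt, lower, upper`` (all ms).
    The default grid is 0–400 ms in 1-ms steps; 3000 replicates of 100
    trials per sigma. Replicate streams are independent per grid point
    (spawned from ``seed``), so results do not depend on evaluation order.
    """
    if sigma_grid is None:
        if sigma_grid_max < 0 or sigma_step <= 0:
            raise ValueError("sigma grid bounds must be non-negative, step > 0")
        sigma_grid = np.arange(0.0, sigma_grid_max + 0.5 * sigma_step, sigma_step)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if sigma_grid.size and sigma_grid.min() < 0:
        raise ValueError("sigma grid must be non-negative")
    streams = np.random.SeedSequence(seed).spawn(sigma_grid.size)
    rows = []
    for s, ss in zip(sigma_grid, streams):
        t_opt, lo, hi = bootstrap_ci_at_sigma(
            g, float(s), n_replicates, n_trials, rng=np.random.default_rng(ss)
        )
        rows.append((float(s), t_opt, lo, hi))
    return pd.DataFrame(rows, columns=["sigma", "t_opt", "lower", "upper"])


def ci_lookup(ci_table: pd.DataFrame, sigma: float) -> pd.Series:
    """CI row at the grid sigma nearest ``sigma`` (error if off-grid by more
    than one step)."""
    sigmas = ci_table["sigma"].to_numpy()
    i = int(np.argmin(np.abs(sigmas - sigma)))
    step = np.median(np.diff(sigmas)) if sigmas.size > 1 else np.inf
    if abs(sigmas[i] - sigma) > step:
        raise ValueError(
            f"sigma {sigma:.1f} ms outside the CI grid [{sigmas.min():.0f}, "
            f"{sigmas.max():.0f}]"
        )
    return ci_table.iloc[i]


def empirical_optimum(
    times,
    g: GainFunction,
    shift_min: float = -1500.0,
    shift_max: float = 1500.0,
    shift_step: float = 1.0,
) -> EmpiricalOptimum:
    """Shift the observed sample along the time axis to maximize total gain.

    Ties over the shift grid are broken by the smallest |s|, then by the
    negative one. Expects outlier-cleaned times.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("no trials supplied")
    if times.size < 2:
        raise ValueError("need at least 2 trials")
    shifts = np.arange(shift_min, shift_max + 0.5 * shift_step, shift_step)
    totals = g(times[None, :] + shifts[:, None]).sum(axis=1)
    best = totals.max()
    tied = shifts[totals >= best - 1e-9 * max(1.0, abs(best))]
    s_star = float(tied[np.lexsort((tied, np.abs(tied)))[0]])
    mean = float(times.mean())
    return EmpiricalOptimum(
        observed_mean_time=mean,
        optimal_shift=s_star,
        optimal_mean_time=mean + s_star,
        observed_total_gain=float(g(times).sum()),
        optimal_total_gain=float(best),
    )


def classify_strategy(
    observed_mean: float,
    ci: tuple[float, float] | pd.Series,
    condition_label: str,
) -> RiskClassification:
    """Risk-attitude label from the observed mean and the optimal-time CI.

    In ``risk_after`` the penalty region is after the target, so means above
    the CI (toward the boundary) are risk-seeking and means below it are
    risk-averse; ``risk_before`` mirrors this.
    """
    if condition_label not in RISK_CONDITIONS:
        raise ValueError(f"classification defined only for {RISK_CONDITIONS}")
    if isinstance(ci, pd.Series):
        lo, hi = float(ci["lower"]), float(ci["upper"])
    else:
        lo, hi = float(ci[0]), float(ci[1])
    if lo > hi:
        raise ValueError("CI lower bound exceeds upper bound")
    if lo <= observed_mean <= hi:
        label = "risk_neutral"
    elif observed_mean > hi:
        label = "risk_seeking" if condition_label == "risk_after" else "risk_averse"
    else:
        label = "risk_averse" if condition_label == "risk_after" else "risk_seeking"
    return RiskClassification(label, float(observed_mean), (lo, hi), condition_label)
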