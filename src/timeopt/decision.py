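"""Expected gain under Gaussian response noise and the optimal planned time.

The decision maker chooses a planned response time ``T``; the executed time
``t`` is Gaussian around it with motor SD ``sigma``. The expected gain

    EG(T) = integral of G(t) * N(t; T, sigma^2) dt

is computed exactly, segment by segment, because the gain is piecewise
linear: over an interval (a, b] with gain m*t + c the contribution is

    m * (T * (Phi(z_b) - Phi(z_a)) - sigma * (phi(z_b) - phi(z_a)))
      + c * (Phi(z_b) - Phi(z_a)),      z = (bound - T) / sigma,

the truncated-normal first-moment identity. The maximizing plan ``T*`` is
the risk-neutral optimum: for the symmetric gains it sits exactly at the
target; for the one-sided risky gains it backs away from the zero-gain
boundary as sigma grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .gains import GainFunction

_SQRT2PI = math.sqrt(2.0 * math.pi)


def _phi(z):
    """Standard normal pdf (ufunc-fast; vanishes at +-inf)."""
    z = np.asarray(z, dtype=float)
    return np.exp(-0.5 * z * z) / _SQRT2PI

# Fractional EG difference treated as a tie during optimization; ties go to
# the planned time nearest the target.
_TIE_REL = 1e-9
# golden-section iterations: shrinks a 2-ms bracket far below the numerical
# noise floor of EG (~1e-5 ms), so T* is limited by curvature/noise only
_GOLDEN_ITERS = 90


@dataclass(frozen=True)
class OptimalPlan:
    """The expected-gain-maximizing planned time for one (gain, sigma)."""

    optimal_time: float  # T*, ms
    optimal_expected_gain: float  # EG(T*), points per trial
    sigma_used: float  # ms
    gain_label: str


def expected_gain(g: GainFunction, planned_time, sigma: float):
    """Expected one-trial gain EG(T) for planned time(s) ``planned_time``.

    ``sigma = 0`` degenerates to evaluating the gain at the plan itself.
    Vectorized over ``planned_time``.
    """
    if not np.isfinite(sigma) or sigma < 0:
        raise ValueError("sigma must be finite and >= 0")
    T = np.asarray(planned_time, dtype=float)
    if sigma == 0.0:
        out = g(T)
        return out if np.ndim(planned_time) else float(out)

    edges = np.concatenate(([-np.inf], np.asarray(g.breakpoints), [np.inf]))
    out = np.zeros_like(T, dtype=float)
    for i, (m, c) in enumerate(zip(g.slopes, g.intercepts)):
        lo, hi = edges[i], edges[i + 1]
        z_lo = (lo - T) / sigma
        z_hi = (hi - T) / sigma
        dPhi = ndtr(z_hi) - ndtr(z_lo)
        if m != 0.0:
            dphi = _phi(z_hi) - _phi(z_lo)
            out += m * (T * dPhi - sigma * dphi) + c * dPhi
        else:
            out += c * dPhi
    return out if np.ndim(planned_time) else float(out)


def expected_gain_curve(g: GainFunction, grid, sigma: float) -> np.ndarray:
    """Two-column array (planned time ms, EG points) over ``grid``."""
    grid = np.asarray(grid, dtype=float)
    return np.column_stack([grid, expected_gain(g, grid, sigma)])


def _golden_max(f, lo: float, hi: float, iters: int = _GOLDEN_ITERS) -> float:
    """Golden-section maximization of a unimodal ``f`` on [lo, hi]."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
        if b - a <= 1e-9:
            break
    return 0.5 * (a + b)


def optimal_plan(g: GainFunction, sigma: float) -> OptimalPlan:
    """Planned time maximizing EG, by 1-ms grid search plus golden-section
    refinement.

    The grid spans target ± (6*sigma + 500) ms, wide enough that the optimum
    of any canonical gain lies strictly inside. Ties (within numerical
    tolerance) resolve to the planned time closest to the target, then to
    the smaller time; ``sigma = 0`` reduces to the argmax of the gain
    itself, with the same tie rule.
    """
    if not np.isfinite(sigma) or sigma < 0:
        raise ValueError("sigma must be finite and >= 0")
    target = g.target
    half = 6.0 * sigma + 500.0
    grid = target + np.arange(-math.ceil(half), math.ceil(half) + 1, dtype=float)

    eg = expected_gain(g, grid, sigma)
    best_val = eg.max()
    tol = _TIE_REL * max(1.0, abs(best_val))
    tied = grid[eg >= best_val - tol]
    # closest to target, then smaller
    t_best = tied[np.lexsort((tied, np.abs(tied - target)))][0]

    if sigma == 0.0:
        return OptimalPlan(float(t_best), float(g(t_best)), 0.0, g.label)

    f = lambda T: expected_gain(g, T, sigma)
    t_star = _golden_max(f, t_best - 1.0, t_best + 1.0)
    # tie rule at full precision: prefer the target when it does as well
    if abs(target - t_best) <= half and f(target) >= f(t_star) - tol:
        t_star = target
    return OptimalPlan(float(t_star), float(f(t_star)), float(sigma), g.label)


def stationarity_residual(gain_label: str, planned_time: float, sigma: float,
                          target: float = 2300.0) -> float:
    """Analytic first-order optimality residual for the risky gains.

    For ``risk_after``, dEG/dT is proportional to
    ``Phi(z) - (target/sigma) * phi(z)`` with ``z = (target - T)/sigma``;
    the residual vanishes exactly at T*. ``risk_before`` uses the mirror
    image about the target. Serves as an independent check on the numeric
    optimizer.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if gain_label == "risk_after":
        z = (target - planned_time) / sigma
        return float(ndtr(z) - (target / sigma) * _phi(z))
    if gain_label == "risk_before":
        return -stationarity_residual("risk_after", 2.0 * target - planned_time,
                                      sigma, target)
    raise ValueError("stationarity residual defined only for risk_after/risk_before")
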