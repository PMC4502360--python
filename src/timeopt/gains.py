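"""Piecewise-linear gain functions for the coincident timing task.

A gain function maps an executed response time (ms) to the points earned on
one trial. The four canonical configurations share a 2300-ms target and a
100-point maximum:

* ``no_risk`` — a symmetric tent: points rise linearly to 100 at the target
  and fall symmetrically after it; every response earns something.
* ``step`` — 100 points anywhere within ±400 ms of the target, 0 outside.
* ``risk_after`` — the rising flank of the tent only; any response after the
  target earns 0 (the penalty region sits *after* the target).
* ``risk_before`` — the mirror image: responses before the target earn 0.

Gains are represented exactly as breakpoints plus per-interval affine
pieces, so downstream expectations under Gaussian response noise can be
computed in closed form segment by segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

DEFAULT_TARGET = 2300.0
MAX_GAIN = 100.0

CANONICAL_LABELS = ("no_risk", "step", "risk_after", "risk_before")


@dataclass(frozen=True)
class GainFunction:
    """A piecewise-linear map from response time (ms) to points.

    Parameters
    ----------
    breakpoints : tuple of float
        Strictly increasing interior breakpoints. With ``k`` breakpoints
        there are ``k + 1`` affine pieces covering the whole real line.
    slopes, intercepts : tuple of float
        Per-piece slope (points/ms) and intercept (points); piece ``i``
        covers times between breakpoint ``i-1`` and breakpoint ``i``.
    belongs : tuple of str
        For each breakpoint, ``"left"`` or ``"right"``: which adjacent piece
        the boundary time itself belongs to. Follows the printed inequality
        of each canonical definition (e.g. ``t <= 2300`` puts 2300 on the
        left piece).
    label : str
        One of the canonical labels or ``"custom"``.
    target : float
        Target time in ms (the 100-point time for the canonical gains).
    """

    breakpoints: tuple[float, ...]
    slopes: tuple[float, ...]
    intercepts: tuple[float, ...]
    belongs: tuple[str, ...]
    label: str = "custom"
    target: float = DEFAULT_TARGET

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        if bp.size + 1 != len(self.slopes) or len(self.slopes) != len(self.intercepts):
            raise ValueError("need exactly one affine piece per interval")
        if bp.size != len(self.belongs):
            raise ValueError("need one boundary-membership flag per breakpoint")
        if bp.size and not np.all(np.diff(bp) > 0):
            raise ValueError("breakpoints must be strictly increasing")
        if not all(b in ("left", "right") for b in self.belongs):
            raise ValueError("boundary membership must be 'left' or 'right'")
        if not np.all(np.isfinite(bp)):
            raise ValueError("breakpoints must be finite")

    # -- evaluation ---------------------------------------------------

    def piece_index(self, t):
        """Index of the affine piece containing each time in ``t``."""
        t = np.asarray(t, dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError("response time must be finite")
        bp = np.asarray(self.breakpoints)
        # default: a boundary belongs to the piece on its right
        idx = np.searchsorted(bp, t, side="right")
        for i, b in enumerate(self.belongs):
            if b == "left":
                idx = np.where(t == bp[i], i, idx)
        return idx

    def __call__(self, t):
        t_arr = np.asarray(t, dtype=float)
        idx = self.piece_index(t_arr)
        slopes = np.asarray(self.slopes)
        intercepts = np.asarray(self.intercepts)
        out = slopes[idx] * t_arr + intercepts[idx]
        if np.isscalar(t) or np.ndim(t) == 0:
            return float(out)
        return out

    @property
    def max_gain(self) -> float:
        """Largest attainable gain (canonical gains: 100 points).

        For an affine piece the supremum over its interval is attained at an
        endpoint; unbounded pieces with nonzero slope make the gain
        unbounded and raise.
        """
        bp = list(self.breakpoints)
        edges = [-np.inf] + bp + [np.inf]
        best = -np.inf
        for i, (m, c) in enumerate(zip(self.slopes, self.intercepts)):
            lo, hi = edges[i], edges[i + 1]
            if m == 0:
                best = max(best, c)
                continue
            if (m > 0 and np.isinf(hi)) or (m < 0 and np.isinf(lo)):
                raise ValueError("gain is unbounded above")
            best = max(best, m * (hi if m > 0 else lo) + c)
        return float(best)

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "target": float(self.target),
            "breakpoints": [float(b) for b in self.breakpoints],
            "slopes": [float(s) for s in self.slopes],
            "intercepts": [float(c) for c in self.intercepts],
            "belongs": list(self.belongs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GainFunction":
        return cls(
            breakpoints=tuple(d["breakpoints"]),
            slopes=tuple(d["slopes"]),
            intercepts=tuple(d["intercepts"]),
            belongs=tuple(d["belongs"]),
            label=d.get("label", "custom"),
            target=float(d.get("target", DEFAULT_TARGET)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "GainFunction":
        return cls.from_dict(yaml.safe_load(text))


def evaluate(g: GainFunction, t):
    """Points earned for a response at time ``t`` (ms) under gain ``g``."""
    return g(t)


# -- canonical constructors -------------------------------------------


def make_no_risk(target: float = DEFAULT_TARGET) -> GainFunction:
    """Symmetric tent gain: G(t) = t/(target/100) up to the target, then the
    mirrored descending flank. Maximum 100 points exactly at the target."""
    k = MAX_GAIN / target  # points per ms on the rising flank
    return GainFunction(
        breakpoints=(target,),
        slopes=(k, -k),
        intercepts=(0.0, 2 * MAX_GAIN),
        belongs=("left",),  # t <= target on the rising piece
        label="no_risk",
        target=target,
    )


def make_step(target: float = DEFAULT_TARGET, half_width: float = 400.0) -> GainFunction:
    """All-or-none gain: 100 points on the closed window target ± half_width."""
    return GainFunction(
        breakpoints=(target - half_width, target + half_width),
        slopes=(0.0, 0.0, 0.0),
        intercepts=(0.0, MAX_GAIN, 0.0),
        belongs=("right", "left"),  # closed interval at both ends
        label="step",
        target=target,
    )


def make_risk_after(target: float = DEFAULT_TARGET) -> GainFunction:
    """Rising flank only: gain grows to 100 at the target, 0 strictly after."""
    k = MAX_GAIN / target
    return GainFunction(
        breakpoints=(target,),
        slopes=(k, 0.0),
        intercepts=(0.0, 0.0),
        belongs=("left",),  # t <= target rewarded
        label="risk_after",
        target=target,
    )


def make_risk_before(target: float = DEFAULT_TARGET) -> GainFunction:
    """Mirror of ``risk_after`` about the target: 0 strictly before the
    target, then a descending flank from 100."""
    k = MAX_GAIN / target
    return GainFunction(
        breakpoints=(target,),
        slopes=(0.0, -k),
        intercepts=(0.0, 2 * MAX_GAIN),
        belongs=("right",),  # t >= target rewarded
        label="risk_before",
        target=target,
    )


_FACTORIES = {
    "no_risk": make_no_risk,
    "step": make_step,
    "risk_after": make_risk_after,
    "risk_before": make_risk_before,
}


def make_gain(label: str, target: float = DEFAULT_TARGET) -> GainFunction:
    """Canonical gain function by label."""
    try:
        factory = _FACTORIES[label]
    except KeyError:
        raise ValueError(
            f"unknown gain label {label!r}; expected one of {CANONICAL_LABELS}"
        ) from None
    return factory(target=target)
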