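"""Per-trial preprocessing and the trial-by-trial compensation analysis.

A session is one participant x condition block of (ordered) response times.
Preprocessing flags outliers beyond ±2.5 SD of the session mean and scores
each trial through the condition's gain function; a *miss* is any trial
earning zero points. The compensation analysis asks how the response on
trial n+1 reacts to the error on trial n:

    compensation_n = RT_{n+1} - RT_n
    error_n        = RT_n - mean(RT)        (session mean, outliers removed)

Errors are binned in units of M = |mean RT - target|, the participant's own
distance from the target, so that participants with different variability
and different risk appetites can be pooled: bins (-2M,-M], (-M,0], (0,M],
(M,2M]. The outermost bin on the penalty side contains exactly the miss
trials, which is what lets post-miss overcompensation be read off as a
bin-4 (or bin-1) excess against a no-risk baseline at matched error size.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gains import GainFunction

TRIAL_COLUMNS = ["participant_id", "condition", "trial_index", "response_time_ms"]
OUTLIER_SD = 2.5
BIN_LABELS = ("bin1", "bin2", "bin3", "bin4")


# ---------------------------------------------------------------- sessions


def filter_outliers(times, threshold: float = OUTLIER_SD) -> np.ndarray:
    """Boolean mask of trials more than ``threshold`` SDs from the session
    mean (single pass: mean and SD include all trials)."""
    times = np.asarray(times, dtype=float)
    if times.size < 3:
        raise ValueError("need at least 3 trials to flag outliers")
    sd = times.std(ddof=1)
    if sd == 0.0:
        return np.zeros(times.size, dtype=bool)
    return np.abs(times - times.mean()) > threshold * sd


def score_trials(times, g: GainFunction, threshold: float = OUTLIER_SD) -> pd.DataFrame:
    """Score one session: per-trial gain, miss flag (gain == 0), outlier flag.

    Returns a frame with ``trial_index`` (1-based), ``response_time_ms``,
    ``gain``, ``miss``, ``outlier``; the cumulative total gain over
    non-excluded trials is attached as ``frame.attrs["total_gain"]``.
    """
    times = np.asarray(times, dtype=float)
    gain = np.asarray(g(times), dtype=float)
    outlier = filter_outliers(times, threshold)
    frame = pd.DataFrame(
        {
            "trial_index": np.arange(1, times.size + 1),
            "response_time_ms": times,
            "gain": gain,
            "miss": gain == 0.0,
            "outlier": outlier,
        }
    )
    frame.attrs["total_gain"] = float(gain[~outlier].sum())
    return frame


def m_statistic(times, target: float = 2300.0, outlier_mask=None) -> float:
    """M = |mean response time - target|, the bin-scaling unit (ms)."""
    times = np.asarray(times, dtype=float)
    if outlier_mask is not None:
        times = times[~np.asarray(outlier_mask, dtype=bool)]
    if times.size == 0:
        raise ValueError("no trials left to compute M")
    return float(abs(times.mean() - target))


@dataclass(frozen=True)
class CompensationTable:
    """Mean trial-to-trial compensation per error bin for one session."""

    M: float  # ms
    convention: str  # "exp1" (left-open] or "exp2" [right-open)
    bin_edges: tuple[float, ...]  # (-2M, -M, 0, M, 2M)
    bin_means: np.ndarray  # 4 values, ms (NaN where a bin is empty)
    bin_counts: np.ndarray  # 4 ints

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": BIN_LABELS,
                "lower": self.bin_edges[:-1],
                "upper": self.bin_edges[1:],
                "mean_compensation": self.bin_means,
                "n_pairs": self.bin_counts,
            }
        )


def compensation_table(
    times,
    M: float,
    convention: str = "exp1",
    outlier_mask=None,
) -> CompensationTable:
    """Bin lag-1 compensations by the size of the preceding error.

    ``convention`` selects boundary membership: ``exp1`` bins are open on
    the left and closed on the right, ``exp2`` the reverse. Errors outside
    [-2M, 2M] are excluded, as are pairs touching an outlier trial and the
    final trial (no successor).
    """
    if M <= 0:
        raise ValueError("M must be > 0")
    if convention not in ("exp1", "exp2"):
        raise ValueError("convention must be 'exp1' or 'exp2'")
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 ordered trials")
    if outlier_mask is None:
        outlier_mask = np.zeros(times.size, dtype=bool)
    outlier_mask = np.asarray(outlier_mask, dtype=bool)

    mean_rt = times[~outlier_mask].mean()
    err = times[:-1] - mean_rt
    comp = np.diff(times)
    valid = ~outlier_mask[:-1] & ~outlier_mask[1:]

    edges = M * np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    # exp1: edges[i-1] < err <= edges[i]; exp2: edges[i-1] <= err < edges[i]
    idx = np.digitize(err, edges, right=(convention == "exp1"))
    means = np.full(4, np.nan)
    counts = np.zeros(4, dtype=int)
    for b in range(1, 5):
        sel = valid & (idx == b)
        counts[b - 1] = int(sel.sum())
        if counts[b - 1]:
            means[b - 1] = comp[sel].mean()
    return CompensationTable(float(M), convention, tuple(edges), means, counts)


def split_half_check(times, outlier_mask=None) -> dict:
    """Compare mean response time over the first and second half of a block.

    Designed for 100-trial sessions (halves of 50); other lengths split
    proportionally with a warning flag. Returns the two means (outliers
    excluded) and a two-sample t-test between the halves.
    """
    times = np.asarray(times, dtype=float)
    if outlier_mask is None:
        outlier_mask = np.zeros(times.size, dtype=bool)
    outlier_mask = np.asarray(outlier_mask, dtype=bool)
    half = times.size // 2
    nonstandard = times.size != 100
    a = times[:half][~outlier_mask[:half]]
    b = times[half:][~outlier_mask[half:]]
    if a.size < 2 or b.size < 2:
        raise ValueError("each half needs at least 2 non-outlier trials")
    if np.array_equal(a, b):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b)
    return {
        "mean_first": float(a.mean()),
        "mean_last": float(b.mean()),
        "t": float(t),
        "df": int(a.size + b.size - 2),
        "p": float(p),
        "nonstandard_length": bool(nonstandard),
    }


def paired_stats(a, b) -> dict:
    """Paired t-test and paired Cohen's d (mean difference / SD of
    differences) for matched per-participant values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero variance of paired differences")
    t, p = stats.ttest_rel(a, b)
    return {
        "t": float(t),
        "df": int(a.size - 1),
        "p": float(p),
        "cohen_d": float(d.mean() / sd),
    }


# ---------------------------------------------------------------- trial logs


def read_trial_log(path_or_buffer) -> pd.DataFrame:
    """Read a trial log (CSV: participant_id, condition, trial_index,
    response_time_ms), validating the required columns."""
    frame = pd.read_csv(path_or_buffer, comment="#")
    for col in TRIAL_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"trial log is missing required column {col!r}")
    frame = frame.sort_values(["participant_id", "condition", "trial_index"])
    return frame.reset_index(drop=True)


def write_trial_log(frame: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a trial log as CSV; optional metadata goes in '#'-prefixed
    header lines (ignored by :func:`read_trial_log` via pandas comment)."""
    buf = io.StringIO()
    if metadata:
        for k, v in sorted(metadata.items()):
            buf.write(f"# {k}: {v}\n")
    frame.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def annotate_trials(frame: pd.DataFrame, gain_map: dict[str, GainFunction],
                    threshold: float = OUTLIER_SD) -> pd.DataFrame:
    """Score every participant x condition session in a trial log.

    ``gain_map`` maps condition labels to gain functions. Adds ``gain``,
    ``miss`` and ``outlier`` columns.
    """
    frame = frame.sort_values(["participant_id", "condition", "trial_index"])
    out = []
    for (pid, cond), grp in frame.groupby(["participant_id", "condition"], sort=False):
        if cond not in gain_map:
            raise ValueError(f"no gain function supplied for condition {cond!r}")
        scored = score_trials(grp["response_time_ms"].to_numpy(), gain_map[cond],
                              threshold)
        grp = grp.copy()
        grp[["gain", "miss", "outlier"]] = scored[["gain", "miss", "outlier"]].to_numpy()
        out.append(grp)
    return pd.concat(out, ignore_index=True)
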