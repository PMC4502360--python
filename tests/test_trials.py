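"""Outlier filtering, scoring, M-binned compensation, split-half, paired t."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from timeopt import gains, trials


# ------------------------------------------------------------- outliers


def test_gross_outlier_flagged():
    times = np.r_[np.full(99, 2300.0) + np.linspace(-1, 1, 99), 9999.0]
    mask = trials.filter_outliers(times)
    assert mask.sum() == 1 and mask[-1]


def test_identical_trials_none_flagged():
    assert trials.filter_outliers(np.full(10, 2300.0)).sum() == 0


def test_too_few_trials():
    with pytest.raises(ValueError):
        trials.filter_outliers(np.array([2300.0, 2301.0]))


def test_expected_flag_rate_gaussian(rng):
    """Mean flags per 100-trial Gaussian session is near
    100 * P(|Z| > 2.5) = 1.24 over 1000 sessions."""
    counts = [trials.filter_outliers(rng.normal(2300, 100, 100)).sum()
              for _ in range(1000)]
    expected = 100 * 2 * norm.sf(2.5)
    assert np.mean(counts) == pytest.approx(expected, rel=0.20)
    # never removes more than ~5% of a Gaussian session on average
    assert np.mean(counts) < 5.0


# ------------------------------------------------------------- scoring


def test_score_trials_labels(canonical):
    times = np.array([2400.0, 2285.0, 2100.0, 2300.0])
    ra = trials.score_trials(times, canonical["risk_after"])
    assert bool(ra.loc[0, "miss"]) and ra.loc[0, "gain"] == 0.0
    st = trials.score_trials(times, canonical["step"])
    assert not st["miss"].any()
    assert st.attrs["total_gain"] == 400.0


def test_no_risk_sessions_never_miss(canonical, rng):
    times = rng.normal(2300, 250, size=200)
    scored = trials.score_trials(times, canonical["no_risk"])
    assert not scored["miss"].any()


# ------------------------------------------------------------- M statistic


@pytest.mark.parametrize("mean, M", [(2146.2, 153.8), (2494.5, 194.5)])
def test_m_statistic(mean, M):
    times = mean + np.array([-10.0, 0.0, 10.0])
    assert trials.m_statistic(times) == pytest.approx(M, abs=1e-9)


def test_m_statistic_degenerate():
    assert trials.m_statistic(np.full(5, 2300.0)) == 0.0
    with pytest.raises(ValueError):
        trials.m_statistic(np.array([2300.0]), outlier_mask=np.array([True]))
    with pytest.raises(ValueError):
        trials.compensation_table(np.array([2300.0, 2310.0]), M=0.0)


# ------------------------------------------------------------- compensation


def test_alternating_sequence_bins():
    """RTs alternating +-100 around 2150: every compensation is +-200 and
    mirror bins have opposite-signed means."""
    times = np.tile([2100.0, 2300.0], 20)
    tab = trials.compensation_table(times, M=150.0, convention="exp1")
    # errors are -100 (bin 2) and +100 (bin 3)
    assert tab.bin_counts[0] == 0 and tab.bin_counts[3] == 0
    assert tab.bin_means[1] == pytest.approx(200.0)
    assert tab.bin_means[2] == pytest.approx(-200.0)


def test_bin_edge_conventions():
    """error = +M goes to bin 3 under exp1 (right-closed) but bin 4 under
    exp2 (left-closed); errors beyond 2M are always excluded."""
    M = 100.0
    # construct two trials: error of first trial exactly +M, then return
    times = np.array([2400.0, 2200.0, 2300.0, 2300.0])  # mean 2300
    exp1 = trials.compensation_table(times, M, "exp1")
    exp2 = trials.compensation_table(times, M, "exp2")
    assert exp1.bin_counts[2] >= 1 and exp1.bin_counts[3] == 0
    assert exp2.bin_counts[3] >= 1
    # errors at +-2.4 M excluded under either convention
    times = np.array([2540.0, 2060.0, 2300.0, 2300.0])  # errors +240, -240, 0
    tab = trials.compensation_table(times, M, "exp1")
    assert tab.bin_counts.sum() == 1  # only the zero-error pair survives
    with pytest.raises(ValueError):
        trials.compensation_table(times, M, "exp3")


def test_outlier_pairs_dropped():
    times = np.r_[np.full(20, 2300.0) + np.tile([-50.0, 50.0], 10), 9000.0,
                  np.full(20, 2300.0) + np.tile([-50.0, 50.0], 10)]
    mask = trials.filter_outliers(times)
    assert mask[20]
    tab = trials.compensation_table(times, M=100.0, outlier_mask=mask)
    # pairs (20, 21) and (19, 20) both touch the outlier and are dropped
    assert tab.bin_counts.sum() == times.size - 1 - 2


def test_lag1_slope_recovery(rng):
    """For RT_{n+1} = plan - beta (RT_n - plan) + eps the regression of
    compensation on error has slope -(1 + beta)."""
    beta, plan, sigma, n = 0.3, 2150.0, 100.0, 100
    slopes = []
    for _ in range(200):
        rt = np.empty(n)
        rt[0] = plan + rng.normal(0, sigma)
        for i in range(n - 1):
            rt[i + 1] = plan - beta * (rt[i] - plan) + rng.normal(0, sigma)
        err = rt[:-1] - rt.mean()
        comp = np.diff(rt)
        slopes.append(np.polyfit(err, comp, 1)[0])
    slopes = np.asarray(slopes)
    se = slopes.std(ddof=1) / np.sqrt(slopes.size)
    assert abs(slopes.mean() - (-(1 + beta))) < 3 * se


# ------------------------------------------------------------- split half


def test_split_half_identical_halves():
    times = np.tile(np.linspace(2200, 2400, 50), 2)
    res = trials.split_half_check(times)
    assert res["t"] == 0.0 and res["mean_first"] == res["mean_last"]
    assert not res["nonstandard_length"]


def test_split_half_type_i_error_rate(rng):
    """A stationary i.i.d. agent triggers the per-session test at ~5%."""
    rejections = [trials.split_half_check(rng.normal(2150, 100, 100))["p"] < 0.05
                  for _ in range(1000)]
    assert 0.03 <= np.mean(rejections) <= 0.07


def test_split_half_power_against_drift(rng):
    """A +100 ms shift between halves at sigma=100 is detected > 90% of the
    time (theoretical power ~ 0.999 at d = 1, n = 50 + 50)."""
    hits = []
    for _ in range(200):
        times = np.r_[rng.normal(2100, 100, 50), rng.normal(2200, 100, 50)]
        hits.append(trials.split_half_check(times)["p"] < 0.05)
    assert np.mean(hits) > 0.90


def test_split_half_nonstandard_length_flag(rng):
    res = trials.split_half_check(rng.normal(2300, 50, 60))
    assert res["nonstandard_length"]


# ------------------------------------------------------------- paired stats


def test_paired_stats_known_values():
    a = np.array([11.0, 12.0, 13.0, 14.0])
    b = np.array([10.0, 10.0, 10.0, 10.0])
    res = trials.paired_stats(a, b)  # differences 1..4
    assert res["t"] == pytest.approx(2.5 / (np.std([1, 2, 3, 4], ddof=1) / 2),
                                     abs=1e-9)
    assert res["t"] == pytest.approx(3.873, abs=1e-3)
    assert res["df"] == 3
    assert res["cohen_d"] == pytest.approx(2.5 / np.std([1, 2, 3, 4], ddof=1))


def test_paired_stats_errors():
    with pytest.raises(ValueError):
        trials.paired_stats([1.0, 2.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):  # zero-variance differences
        trials.paired_stats([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
    res = trials.paired_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.1])
    assert res["p"] > 0  # sanity: non-degenerate case runs


# ------------------------------------------------------------- trial logs


def test_trial_log_roundtrip(tmp_path, canonical, rng):
    frame = pd.DataFrame({
        "participant_id": "P01",
        "condition": "risk_after",
        "trial_index": np.arange(1, 21),
        "response_time_ms": rng.normal(2150, 120, 20),
    })
    path = tmp_path / "log.csv"
    trials.write_trial_log(frame, path, metadata={"seed": 1})
    loaded = trials.read_trial_log(path)
    np.testing.assert_allclose(loaded["response_time_ms"],
                               frame["response_time_ms"])
    annotated = trials.annotate_trials(loaded,
                                       {"risk_after": canonical["risk_after"]})
    assert {"gain", "miss", "outlier"} <= set(annotated.columns)


def test_trial_log_missing_column():
    with pytest.raises(ValueError, match="response_time_ms"):
        trials.read_trial_log(io.StringIO(
            "participant_id,condition,trial_index\nP01,no_risk,1\n"))
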