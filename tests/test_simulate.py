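"""Synthetic-agent generator: policies, lag-1 dynamics, determinism."""

import numpy as np
import pytest

from timeopt import decision, simulate
from timeopt.gains import make_gain


def test_agent_validation():
    with pytest.raises(ValueError):
        simulate.AgentSpec(true_sigma=0.0)
    with pytest.raises(ValueError):
        simulate.AgentSpec(true_sigma=100.0, lag1_beta=1.0)
    with pytest.raises(ValueError):
        simulate.AgentSpec(true_sigma=100.0, alpha=0.0)
    with pytest.raises(ValueError):
        simulate.AgentSpec(true_sigma=100.0, risk_policy="yolo")
    with pytest.raises(ValueError):
        simulate.SessionConfig(n_trials=0)


def test_plan_time_policies(canonical):
    sigma = 150.0
    t_star = decision.optimal_plan(canonical["risk_after"], sigma).optimal_time
    # optimal policy delegates to the decision model
    agent = simulate.AgentSpec(true_sigma=sigma, risk_policy="optimal")
    assert simulate.plan_time(agent, canonical["risk_after"]) == t_star
    # believing sigma is halved pulls the plan toward the target
    misest = simulate.AgentSpec(true_sigma=sigma,
                                risk_policy="variance_misestimation", alpha=0.5)
    t_half = simulate.plan_time(misest, canonical["risk_after"])
    assert t_star < t_half < 2300.0
    assert t_half == decision.optimal_plan(canonical["risk_after"],
                                           0.5 * sigma).optimal_time
    # zero offset is the optimal policy
    zero = simulate.AgentSpec(true_sigma=sigma, risk_policy="fixed_offset",
                              delta=0.0)
    assert simulate.plan_time(zero, canonical["risk_after"]) == t_star
    # offset moves toward the target: later in risk_after, earlier in
    # risk_before
    off = simulate.AgentSpec(true_sigma=sigma, risk_policy="fixed_offset",
                             delta=115.0)
    assert simulate.plan_time(off, canonical["risk_after"]) == \
        pytest.approx(t_star + 115.0)
    t_before = decision.optimal_plan(canonical["risk_before"], sigma) \
        .optimal_time
    assert simulate.plan_time(off, canonical["risk_before"]) == \
        pytest.approx(t_before - 115.0)


def test_iid_session_mean(rng):
    agent = simulate.AgentSpec(true_sigma=120.0)
    cfg = simulate.SessionConfig(condition="risk_after", n_trials=400)
    log = simulate.simulate_session(agent, cfg, rng=rng)
    plan = log.attrs["plan"]
    assert abs(log["response_time_ms"].mean() - plan) < 3 * 120.0 / 20.0
    assert list(log["trial_index"]) == list(range(1, 401))
    assert set(log["foreperiod_ms"]).issubset({800.0, 900.0, 1000.0, 1100.0,
                                               1200.0})


def test_lag1_autocorrelation(rng):
    """beta = 0.3 yields lag-1 autocorrelation ~ -0.3 (AR(1) with
    coefficient -beta)."""
    agent = simulate.AgentSpec(true_sigma=100.0, lag1_beta=0.3)
    cfg = simulate.SessionConfig(condition="no_risk", n_trials=100)
    acs = []
    for _ in range(300):
        rt = simulate.simulate_session(agent, cfg, rng=rng)[
            "response_time_ms"].to_numpy()
        d = rt - rt.mean()
        acs.append((d[:-1] * d[1:]).sum() / (d * d).sum())
    acs = np.asarray(acs)
    se = acs.std(ddof=1) / np.sqrt(acs.size)
    # finite-sample AR(1) autocorrelation estimates are biased toward 0 by
    # O(1/n); allow for it alongside the Monte-Carlo error
    assert abs(acs.mean() - (-0.3)) < 3 * se + 2.0 / 100.0


def test_post_miss_kick_direction(rng):
    """After a miss the next response moves away from the penalty region."""
    for cond, sign in (("risk_after", -1.0), ("risk_before", 1.0)):
        # plan 200 ms closer to the boundary so misses are frequent (~30%)
        agent = simulate.AgentSpec(true_sigma=130.0, post_miss_kappa=500.0,
                                   risk_policy="fixed_offset", delta=200.0)
        cfg = simulate.SessionConfig(condition=cond, n_trials=200)
        log = simulate.simulate_session(agent, cfg, rng=rng)
        rt = log["response_time_ms"].to_numpy()
        miss = log["miss"].to_numpy()
        plan = log.attrs["plan"]
        after_miss = rt[1:][miss[:-1]] - plan
        after_hit = rt[1:][~miss[:-1]] - plan
        assert after_miss.size > 3
        # a 500-ms kick separates the two conditional means decisively
        assert sign * (after_miss.mean() - after_hit.mean()) > 250.0


def test_no_risk_session_never_misses(rng):
    agent = simulate.AgentSpec(true_sigma=250.0)
    cfg = simulate.SessionConfig(condition="no_risk", n_trials=300)
    log = simulate.simulate_session(agent, cfg, rng=rng)
    assert not log["miss"].any()
    assert (log["gain"] > 0).all()


def test_session_determinism():
    agent = simulate.AgentSpec(true_sigma=130.0, lag1_beta=0.2,
                               post_miss_kappa=30.0, seed=99)
    cfg = simulate.SessionConfig(condition="risk_after")
    a = simulate.simulate_session(agent, cfg)
    b = simulate.simulate_session(agent, cfg)
    assert a.equals(b)


def test_cohort_determinism_and_manifest():
    cfg = simulate.SessionConfig(condition="risk_after", n_trials=20)
    log1, man1 = simulate.simulate_cohort(3, cfg, seed=11)
    log2, man2 = simulate.simulate_cohort(3, cfg, seed=11)
    assert log1.equals(log2) and man1 == man2
    assert log1["participant_id"].nunique() == 3
    assert {m["participant_id"] for m in man1} == set(log1["participant_id"])
    with pytest.raises(ValueError):
        simulate.simulate_cohort(0, cfg)
    with pytest.raises(ValueError):
        simulate.simulate_cohort(2, cfg, sigma_median=-1.0)


def test_cohort_sigma_distribution(rng):
    """Empirical median of per-agent sigma near the configured 130 ms."""
    sigmas = simulate.draw_sigmas(1000, 130.0, 0.3, rng)
    assert np.median(sigmas) == pytest.approx(130.0, rel=0.05)
    # the cohort generator uses the same draw
    cfg = simulate.SessionConfig(condition="no_risk", n_trials=3)
    _, manifest = simulate.simulate_cohort(5, cfg, seed=5, sigma_median=130.0)
    assert all(40.0 < m["true_sigma"] < 450.0 for m in manifest)


def test_cohort_fixed_offset_means_cluster_near_shifted_optimum():
    """delta = 115 agents respond ~115 ms later than their own T* in
    risk_after."""
    cfg = simulate.SessionConfig(condition="risk_after", n_trials=100)
    log, manifest = simulate.simulate_cohort(
        8, cfg, policy="fixed_offset", delta=115.0, seed=2)
    gaps = []
    for m in manifest:
        rt = log.loc[log["participant_id"] == m["participant_id"],
                     "response_time_ms"]
        t_star = decision.optimal_plan(make_gain("risk_after"),
                                       m["true_sigma"]).optimal_time
        gaps.append(rt.mean() - t_star)
    assert np.mean(gaps) == pytest.approx(115.0, abs=30.0)
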