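# timeopt

Bayesian decision-theoretic analysis of *when* to act: given a gain function
over response time and a person's own motor variability, where should they
aim — and where do they actually aim?

In a coincident timing task, a participant presses a button as close as
possible to a memorized target interval (2300 ms here) and earns points
through a gain function `G(t)` of the executed response time `t` (in ms).
Executed times scatter around the planned time `T` with Gaussian motor noise
of SD `σ`,

    P(t | T) = N(t; T, σ²),

so a risk-neutral planner maximizes the expected gain

    EG(T) = ∫ G(t) · P(t | T) dt,

and the optimal plan `T* = argmax EG(T)` depends on both the shape of
`G` and on `σ`. Four canonical gain configurations are built in, all with a
100-point maximum:

| label         | shape                                            | optimal plan |
|---------------|--------------------------------------------------|--------------|
| `no_risk`     | symmetric tent peaking at the target             | `T* = 2300`  |
| `step`        | 100 points within ±400 ms of the target          | `T* = 2300`  |
| `risk_after`  | gain rises to 100 at the target, 0 after it      | `T* < 2300`, earlier as σ grows |
| `risk_before` | mirror image: 0 before the target                | `T* > 2300`, later as σ grows |

Because the gains are piecewise linear, `EG(T)` is evaluated in closed form
per segment via the Gaussian CDF/PDF (truncated-normal first moments), and
`T*` is found by a 1-ms grid plus golden-section refinement.

The package is written for researchers in motor control / decision
neuroscience who want to (a) compute optimal timing strategies and their
bootstrap confidence intervals, (b) classify observed behavior as
risk-neutral, risk-seeking, or risk-averse, (c) analyze trial-by-trial error
compensation (including post-miss overcorrection), and (d) validate the
whole pipeline by parameter recovery on synthetic participants.

## What's inside

- `timeopt.gains` — piecewise-linear gain functions, canonical constructors,
  YAML serialization.
- `timeopt.decision` — closed-form `expected_gain`, `optimal_plan`, and an
  analytic stationarity residual for the risky gains.
- `timeopt.inference` — percentile-bootstrap CIs of the optimal mean time
  over a σ grid (3000 resamples of 100-trial sessions by default), the
  model-free distribution-shift optimum, and risk-attitude classification.
- `timeopt.trials` — ±2.5 SD outlier filtering, trial scoring, M-scaled
  compensation bins, split-half learning check, paired t / Cohen's d.
- `timeopt.simulate` — synthetic agents: Gaussian motor noise, optional
  fixed offset toward the boundary, variance misestimation, lag-1 error
  correction with a post-miss kick.
- `timeopt.estimators` — scikit-learn-style wrappers
  (`RiskAttitudeClassifier`, `EmpiricalOptimumEstimator`,
  `CompensationAnalyzer`).
- `timeopt.pipeline` / `timeopt` CLI — config-driven end-to-end runs
  (`simulate`, `analyze`, `report`, `all`).

## Worked example

```python
import numpy as np
from timeopt import decision, gains, simulate
from timeopt.estimators import RiskAttitudeClassifier

# optimal plan for a person with sigma = 150 ms under the risky gain
g = gains.make_risk_after()
plan = decision.optimal_plan(g, 150.0)
print(plan.optimal_time, plan.optimal_expected_gain)
# -> T* = 2012.3 ms, EG(T*) = 84.67 points/trial

# a 16-agent cohort that aims 115 ms closer to the boundary than optimal
cfg = simulate.SessionConfig(condition="risk_after", n_trials=100)
log, _ = simulate.simulate_cohort(16, cfg, policy="fixed_offset", delta=115.0,
                                  lag1_beta=0.3, post_miss_kappa=50.0, seed=42)
X = [grp.sort_values("trial_index")["response_time_ms"].to_numpy()
     for _, grp in log.groupby("participant_id")]
clf = RiskAttitudeClassifier(condition="risk_after", random_state=0).fit(X)
print(clf.labels_)        # all 16: 'risk_seeking'
print(clf.observed_mean_[0], clf.ci_lower_[0], clf.ci_upper_[0])
# -> mean 2121.3 ms vs CI [1937.5, 2008.9] at that agent's sd (178.5 ms)
```

The printed numbers mean: with σ = 150 ms a risk-neutral planner should aim
~288 ms *before* the target (T\* ≈ 2012 ms), collecting ~84.7 of the 100
possible points per trial in expectation. The simulated cohort deliberately
aims 115 ms later than its optimum; every agent's observed mean falls above
the 95% bootstrap CI of the optimal mean time at its own SD, so all 16 are
classified risk-seeking — the detection the classifier exists for.

The same run from a shell:

```sh
timeopt all --seed 42 --condition risk_after --out run1
```

writes `participants.csv`, `table1.csv`, `compensation.csv`,
`split_half.csv` and a `manifest.yaml` under `run1/`.

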