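# Methods

## Model

A trial's executed response time `t` (ms) is Gaussian around the planned
time `T` with motor SD `σ`: `P(t|T) = N(t; T, σ²)`. Points are assigned by a
piecewise-linear gain function `G(t)`; the four canonical configurations
share a 2300-ms target and a 100-point maximum. The risk-neutral plan
maximizes the expected gain `EG(T) = ∫ G(t) P(t|T) dt`.

Boundary membership follows each gain's printed inequality: the no-risk tent
and `risk_after` include the target on the rewarded side (`t ≤ 2300`), the
step window is closed at both ends (`1900 ≤ t ≤ 2700`), and `risk_before`
includes the target (`t ≥ 2300`); at exactly `t = 2300` both risky gains pay
100 points. Membership is measure-zero for the integral but matters for
scoring discrete trials. Gains extend literally over the whole real line
(negative values are possible below `t = 0` for the linear flanks); the
model integrates over the whole line and simulated negative times are kept,
not clipped, because every analysis is translation-based.

## Numerics

**Expected gain** is exact per segment via truncated-normal first moments:
over `(a, b]` with gain `m·t + c`,
`m·(T·ΔΦ − σ·Δφ) + c·ΔΦ` with `z = (bound − T)/σ`. No quadrature is used in
the computation path; adaptive quadrature and Monte Carlo serve only as
independent test oracles. `σ = 0` degenerates to `G(T)`.

**Optimizer.** 1-ms grid over `target ± (6σ + 500)` ms — wide enough to
provably contain the optimum of every canonical gain — followed by
golden-section refinement run effectively to the numerical noise floor of
`EG` (≈1e-5 ms in `T`). The tight refinement matters because the analytic
optimality condition for the risky gains,
`Φ(z) = (target/σ)·φ(z)`, `z = (target − T*)/σ`, is used as an independent
check at 1e-6 tolerance, and its residual changes by ~1e-2 per ms of `T`
error. Expected-gain values within a 1e-9 relative band are treated as ties
and resolved to the planned time closest to the target, then to the smaller
time; this also pins the symmetric optima to exactly 2300.0 rather than
2300 ± noise.

## Bootstrap CI of the optimal mean time

For each σ on a grid (default 0–400 ms in 1-ms steps, matching the range of
human response SDs in this task; the grid is evaluated lazily where only a
few σ values are needed), 3000 sessions of 100 Gaussian trials are simulated
at `(T*(σ), σ)`; the 2.5% and 97.5% points of the session means form the
95% CI. Replicate streams are spawned per grid index from the top-level
seed, so results are identical regardless of evaluation order. At `σ = 0`
the CI collapses to the target.

**Classification** compares a session's observed mean (outliers beyond
±2.5 SD removed) against the CI: inside → risk-neutral; beyond the CI
toward the zero-gain boundary → risk-seeking; away from it → risk-averse.

**Which σ indexes the CI.** On real data the participant's σ is unknown, so
the CI is looked up at the SD of their non-outlier trials in the same risky
condition. The coverage *property* of the CI (an ideal agent is labeled
risk-neutral ~95% of the time) holds only at the agent's true σ: looking up
at the estimated SD propagates the SD's sampling error through the slope of
`T*(σ)` (≈ −1.5 ms per ms of σ in `risk_after`), adding noise comparable to
the CI half-width (≈1.96σ/√100) and lowering empirical coverage to roughly
80%. The coverage tests therefore classify at the known simulation σ, while
the data pipeline uses the measured SD. This is worth remembering when
interpreting borderline classifications of real participants: detection of
offsets much larger than the CI half-width (e.g. ~115 ms) is unaffected.

Outlier filtering slightly trims the session-mean variance (truncation at
±2.5 SD), so empirical coverage sits marginally *above* the nominal 95%
(~96%).

## Distribution-shift optimum

A model-free alternative: translate the observed (outlier-cleaned) sample by
`s` on a ±1500-ms, 1-ms grid and take the shift maximizing total gain
`Σ G(tᵢ + s)`; ties resolve to the smallest |s|, then the negative shift.
The raw sample, not a histogram, is shifted. The optimal shifted mean is
biased toward the target relative to the continuous-Gaussian `T*` by
~15–20 ms at σ = 130, n = 100: a finite sample carries no mass beyond its
maximum, so it can sit closer to the zero-gain cliff than the underlying
distribution safely could. The bias is inherent to the estimator (not a grid
artifact) and stays well within the estimator's single-session SD; tests
check agreement at that resolution.

## Trial-by-trial compensation

`compensation_n = RT_{n+1} − RT_n`, and `error_n = RT_n − mean(RT)` with the
session's own post-exclusion mean (compensation is assumed to operate around
each condition's own mean). Errors are binned at edges
`{−2M, −M, 0, M, 2M}` with `M = |mean RT − target|` taken from the *risky*
condition and reused for the same participant's no-risk session so bins are
matched in error magnitude across conditions. Two printed edge conventions
are supported: `exp1` (left-open, right-closed, used with `risk_after`
cohorts) and `exp2` (closed-left, open-right, used with `risk_before`);
errors outside `[−2M, 2M]` are excluded. Pairs touching an outlier-flagged
trial are dropped entirely (the source analyses are silent on this; keeping
them would inject artifactual giant compensations), as is the final trial.

For a lag-1 agent `RT_{n+1} = plan − β(RT_n − plan) + ε`, the regression of
compensation on error has slope `−(1+β)` and the bin means are antisymmetric
(bin 1 vs bin 4). A post-miss kick of `κ` ms away from the penalty region
shows up as a bin-4 (respectively bin-1) excess of ≈ `κ` over the matched
no-risk bin, up to a `κ·P(miss)` correction from the kick's effect on the
session mean (~3% here); parameter-recovery tests confirm this at 3-SE
resolution over 500 sessions.

## Synthetic participants

The generator emulates the study conditions: 100-trial sessions, target
2300 ms, foreperiods 800–1200 ms in 100-ms steps (logged, not used), and a
cohort of 16 agents whose σ is log-normal with median 130 ms and log-SD 0.3
(bulk between ~70 and ~240 ms, matching the human SD range on this task).
The default behavioral profile formalizes the two candidate explanations of
observed risk-seeking as policies — a fixed 115-ms offset toward the
boundary (matching the observed-minus-optimal gap in the asymmetric
conditions) or optimal planning under a believed SD `α·σ` — plus lag-1
compensation `β = 0.3` and a post-miss kick `κ = 50` ms. `δ = 0`/`α = 1`
reduce to the ideal risk-neutral agent used for coverage tests.

What the generator does *not* emulate: learning or drift across trials
(sessions are stationary by construction, so the split-half check's null
behavior is exact), scalar-timing growth of variance with interval length,
non-Gaussian response distributions, and any foreperiod effect on RT.
Passing recovery tests therefore show the pipeline is correct *given* the
Gaussian stationary model — the same assumption the analysis makes of real
data — not that real data satisfy it.

## Statistical conventions

Paired comparisons use the paired t with `df = n − 1` and paired Cohen's
`d = mean(a−b)/SD(a−b)` (the variant is not standardized in the literature;
the paired form matches the reported within-subject contrasts). Outliers are
flagged in a single pass at ±2.5 SD per participant × condition; flagged
trials are excluded from every downstream mean, SD, and analysis. The
split-half learning check compares means of trials 1–50 vs 51–100
(two-sample t per session; paired t across participants), splitting
proportionally with a flag when a session is not 100 trials. Session totals
are reported on the 100-trial scale (`100 × EG(T*)` for the model optimum).
Repeated-measures ANOVA is deliberately not reimplemented; per-bin paired
t-tests with descriptive means cover the condition × bin comparisons.

## Problem sizes in the default test/validation runs

Chosen as the package's own validation budget: 3000 bootstrap replicates of
100 trials; 1000 sessions for CI coverage; 500 paired sessions for
compensation recovery; 16-agent cohorts for detection checks; 50 random
cases for closed-form-vs-quadrature agreement at 1e-6 points.

## Known limitations

- The percentile bootstrap is the plain variant (no BCa/studentizing).
- Classification at the estimated σ inherits lookup noise (above); the CI
  curve itself is exact up to Monte-Carlo error.
- The compensation analysis conditions on bins of `error_n` but not on
  longer lags; agents with richer-than-lag-1 dynamics would alias into β.
- `M = 0` (mean exactly at the target) makes the bin scale degenerate; such
  sessions are skipped with the condition surfaced to the caller.
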