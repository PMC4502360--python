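"""scikit-learn-style estimators over the timing-strategy analyses.

Each estimator consumes sessions of response times — ``X`` is an array of
shape ``(n_sessions, n_trials)`` or a list of 1-D arrays — and exposes the
analysis results as fitted attributes. They follow sklearn conventions
(``get_params``/``set_params``, validation in ``fit``, trailing-underscore
attributes) and clone/compose with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import inference, trials
from .gains import make_gain


def _as_sessions(X) -> list[np.ndarray]:
    if isinstance(X, np.ndarray) and X.ndim == 1:
        X = [X]
    sessions = [np.asarray(row, dtype=float).ravel() for row in X]
    if not sessions:
        raise ValueError("X must contain at least one session")
    for s in sessions:
        if s.size < 3:
            raise ValueError("each session needs at least 3 trials")
        if not np.all(np.isfinite(s)):
            raise ValueError("response times must be finite")
    return sessions


class RiskAttitudeClassifier(BaseEstimator):
    """Classify sessions as risk_neutral / risk_seeking / risk_averse.

    For each session the observed mean (outliers beyond ``outlier_sd`` SDs
    removed) is compared with the bootstrap 95% CI of the optimal mean
    response time at that session's motor SD. Means beyond the CI toward
    the zero-gain boundary are risk-seeking.

    Parameters
    ----------
    condition : {"risk_after", "risk_before"}
    target : float, target time in ms.
    n_replicates, n_trials : bootstrap settings (3000 resamples of
        100-trial sessions by default).
    sigma_step : float, granularity of the sigma grid the CI is computed on.
    outlier_sd : float, outlier threshold in SDs.
    random_state : int or None, seeds the bootstrap.
    """

    def __init__(self, condition: str = "risk_after", target: float = 2300.0,
                 n_replicates: int = 3000, n_trials: int = 100,
                 sigma_step: float = 1.0, outlier_sd: float = 2.5,
                 random_state: int | None = None):
        self.condition = condition
        self.target = target
        self.n_replicates = n_replicates
        self.n_trials = n_trials
        self.sigma_step = sigma_step
        self.outlier_sd = outlier_sd
        self.random_state = random_state

    # CI per sigma-grid index, reproducible independent of evaluation order
    def _ci(self, sigma: float):
        idx = int(round(sigma / self.sigma_step))
        if idx not in self._ci_cache:
            ss = np.random.SeedSequence(
                self.random_state if self.random_state is not None else 0,
                spawn_key=(idx,),
            )
            self._ci_cache[idx] = inference.bootstrap_ci_at_sigma(
                self._gain, idx * self.sigma_step, self.n_replicates,
                self.n_trials, rng=np.random.default_rng(ss),
            )
        return self._ci_cache[idx]

    def _analyze(self, sessions, sigma=None):
        n = len(sessions)
        if sigma is not None:
            sigma = np.asarray(sigma, dtype=float).ravel()
            if sigma.size != n:
                raise ValueError("sigma must have one value per session")
        means = np.empty(n)
        sds = np.empty(n)
        for i, s in enumerate(sessions):
            keep = ~trials.filter_outliers(s, self.outlier_sd)
            means[i] = s[keep].mean()
            sds[i] = s[keep].std(ddof=1)
        lookup_sigma = sds if sigma is None else sigma
        t_opt = np.empty(n)
        lo = np.empty(n)
        hi = np.empty(n)
        labels = []
        for i, sg in enumerate(lookup_sigma):
            t_opt[i], lo[i], hi[i] = self._ci(float(sg))
            labels.append(
                inference.classify_strategy(means[i], (lo[i], hi[i]),
                                            self.condition).label
            )
        return means, sds, np.asarray(lookup_sigma, float), t_opt, lo, hi, np.array(labels)

    def fit(self, X, y=None, sigma=None):
        """Fit on sessions; ``sigma`` optionally overrides the estimated
        per-session SD for the CI lookup (e.g. a known simulation SD)."""
        if self.condition not in inference.RISK_CONDITIONS:
            raise ValueError(
                f"condition must be one of {inference.RISK_CONDITIONS}")
        sessions = _as_sessions(X)
        self._gain = make_gain(self.condition, target=self.target)
        self._ci_cache: dict[int, tuple[float, float, float]] = {}
        (self.observed_mean_, self.sigma_, self.lookup_sigma_, self.t_opt_,
         self.ci_lower_, self.ci_upper_, self.labels_) = self._analyze(
            sessions, sigma)
        self.n_sessions_ = len(sessions)
        return self

    def predict(self, X, sigma=None):
        """Risk-attitude labels for new sessions."""
        if not hasattr(self, "labels_"):
            raise RuntimeError("fit the classifier first")
        return self._analyze(_as_sessions(X), sigma)[-1]


class EmpiricalOptimumEstimator(BaseEstimator):
    """Distribution-shift optimum per session (model-free optimal time).

    Translates each session's (outlier-cleaned) response times along the
    time axis to maximize total gain; the shifted mean is that
    distribution's own optimal mean response time.
    """

    def __init__(self, condition: str = "risk_after", target: float = 2300.0,
                 shift_min: float = -1500.0, shift_max: float = 1500.0,
                 shift_step: float = 1.0, outlier_sd: float = 2.5):
        self.condition = condition
        self.target = target
        self.shift_min = shift_min
        self.shift_max = shift_max
        self.shift_step = shift_step
        self.outlier_sd = outlier_sd

    def fit(self, X, y=None):
        sessions = _as_sessions(X)
        g = make_gain(self.condition, target=self.target)
        res = []
        for s in sessions:
            keep = ~trials.filter_outliers(s, self.outlier_sd)
            res.append(inference.empirical_optimum(
                s[keep], g, self.shift_min, self.shift_max, self.shift_step))
        self.observed_mean_ = np.array([r.observed_mean_time for r in res])
        self.shift_ = np.array([r.optimal_shift for r in res])
        self.optimal_mean_time_ = np.array([r.optimal_mean_time for r in res])
        self.observed_total_gain_ = np.array([r.observed_total_gain for r in res])
        self.optimal_total_gain_ = np.array([r.optimal_total_gain for r in res])
        return self

    def transform(self, X):
        """Columns (observed mean, optimal shift, optimal mean time) per
        session."""
        self.fit(X)
        return np.column_stack(
            [self.observed_mean_, self.shift_, self.optimal_mean_time_])


class CompensationAnalyzer(BaseEstimator):
    """Lag-1 compensation binned by preceding error in units of M.

    ``M`` may be given explicitly (one value, or one per session — e.g. a
    participant's M from their risk condition applied to their no-risk
    session) or derived per session as |mean RT - target|.
    """

    def __init__(self, target: float = 2300.0, convention: str = "exp1",
                 M: float | None = None, outlier_sd: float = 2.5):
        self.target = target
        self.convention = convention
        self.M = M
        self.outlier_sd = outlier_sd

    def fit(self, X, y=None, M=None):
        sessions = _as_sessions(X)
        n = len(sessions)
        if M is None:
            M = self.M
        if M is None:
            M_arr = np.full(n, np.nan)
        else:
            M_arr = np.broadcast_to(np.asarray(M, dtype=float).ravel(), (n,)).copy() \
                if np.ndim(M) else np.full(n, float(M))
        self.bin_means_ = np.empty((n, 4))
        self.bin_counts_ = np.empty((n, 4), dtype=int)
        for i, s in enumerate(sessions):
            mask = trials.filter_outliers(s, self.outlier_sd)
            if np.isnan(M_arr[i]):
                M_arr[i] = trials.m_statistic(s, self.target, mask)
            tab = trials.compensation_table(s, M_arr[i], self.convention, mask)
            self.bin_means_[i] = tab.bin_means
            self.bin_counts_[i] = tab.bin_counts
        self.M_ = M_arr
        return self

    def transform(self, X):
        self.fit(X)
        return self.bin_means_
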