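"""End-to-end runs: simulate (or load) trial logs, infer strategies, run the
compensation and learning analyses, and emit report tables.

A single flat config drives everything; every stochastic stage draws its
stream from the top-level seed, so identical config + seed gives byte-
identical outputs. The report bundle mirrors the study's summary artifacts:
a per-participant classification table, an optimal-vs-observed condition
summary, a per-bin compensation table with cross-condition paired tests,
and a split-half learning check.
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, inference, trials
from .decision import expected_gain, optimal_plan
from .gains import make_gain
from .simulate import AgentSpec, SessionConfig, simulate_session

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "target_time": 2300.0,
    "outlier_sd": 2.5,
    "bootstrap": {"n_replicates": 3000, "n_trials": 100, "sigma_step": 1.0},
    "shift_grid": {"min": -1500.0, "max": 1500.0, "step": 1.0},
    # None -> exp1 bins for risk_after cohorts, exp2 for risk_before
    "bin_convention": None,
    "input": None,  # path to a trial log CSV; set to skip simulation
    "simulate": {
        "n_agents": 16,
        "condition": "risk_after",
        "n_trials": 100,
        "include_no_risk": True,
        # behavioral defaults: risk-seeking offset with lag-1 compensation
        # and post-miss overcorrection
        "policy": "fixed_offset",
        "delta": 115.0,
        "alpha": 1.0,
        "lag1_beta": 0.3,
        "post_miss_kappa": 50.0,
        "sigma_median": 130.0,
        "sigma_log_sd": 0.3,
    },
}


def resolve_config(overrides: dict | None = None) -> dict:
    """Defaults deep-merged with ``overrides`` (overrides win)."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(base, extra, path=""):
        for k, v in extra.items():
            here = f"{path}.{k}" if path else k
            if k not in base:
                raise ValueError(f"unknown config field {here!r}")
            if isinstance(base[k], dict) and isinstance(v, dict):
                merge(base[k], v, here)
            else:
                base[k] = v

    if overrides:
        merge(cfg, overrides)
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        return resolve_config(yaml.safe_load(fh) or {})


# ------------------------------------------------------------- simulation


def simulate_from_config(cfg: dict) -> tuple[pd.DataFrame, list[dict]]:
    """Simulate the configured cohort: each agent runs the risk condition
    and (optionally) a paired no-risk session with the same motor SD."""
    sim = cfg["simulate"]
    root = np.random.SeedSequence(cfg["seed"])
    sigma_stream, *agent_streams = root.spawn(sim["n_agents"] + 1)
    sigmas = sim["sigma_median"] * np.exp(
        np.random.default_rng(sigma_stream).normal(
            0.0, sim["sigma_log_sd"], sim["n_agents"])
    )
    conditions = [sim["condition"]]
    if sim["include_no_risk"] and sim["condition"] != "no_risk":
        conditions.append("no_risk")
    logs, manifest = [], []
    width = max(2, len(str(sim["n_agents"])))
    for i, (sig, ss) in enumerate(zip(sigmas, agent_streams)):
        pid = f"P{i + 1:0{width}d}"
        agent = AgentSpec(
            true_sigma=float(sig), risk_policy=sim["policy"],
            delta=sim["delta"], alpha=sim["alpha"],
            lag1_beta=sim["lag1_beta"], post_miss_kappa=sim["post_miss_kappa"],
        )
        entry = {"participant_id": pid, "true_sigma": float(sig),
                 "policy": sim["policy"], "delta": sim["delta"],
                 "alpha": sim["alpha"], "lag1_beta": sim["lag1_beta"],
                 "post_miss_kappa": sim["post_miss_kappa"]}
        for cond, child in zip(conditions, ss.spawn(len(conditions))):
            scfg = SessionConfig(condition=cond, n_trials=sim["n_trials"],
                                 target_time=cfg["target_time"])
            log = simulate_session(agent, scfg,
                                   rng=np.random.default_rng(child),
                                   participant_id=pid)
            entry[f"plan_{cond}"] = log.attrs["plan"]
            logs.append(log)
        manifest.append(entry)
    return pd.concat(logs, ignore_index=True), manifest


# --------------------------------------------------------------- analysis


class _IndexedBootstrap:
    """Percentile CIs on the sigma grid, seeded per grid index so results
    do not depend on lookup order."""

    def __init__(self, gain, cfg, seed_entropy: int):
        self.gain = gain
        self.step = cfg["bootstrap"]["sigma_step"]
        self.n_replicates = cfg["bootstrap"]["n_replicates"]
        self.n_trials = cfg["bootstrap"]["n_trials"]
        self.entropy = seed_entropy
        self._cache: dict[int, tuple[float, float, float]] = {}

    def at(self, sigma: float) -> tuple[float, float, float]:
        idx = int(round(sigma / self.step))
        if idx not in self._cache:
            ss = np.random.SeedSequence(self.entropy, spawn_key=(idx,))
            self._cache[idx] = inference.bootstrap_ci_at_sigma(
                self.gain, idx * self.step, self.n_replicates, self.n_trials,
                rng=np.random.default_rng(ss))
        return self._cache[idx]


def _session_arrays(frame: pd.DataFrame):
    for (pid, cond), grp in frame.groupby(["participant_id", "condition"],
                                          sort=True):
        grp = grp.sort_values("trial_index")
        yield pid, cond, grp["response_time_ms"].to_numpy()


def analyze(frame: pd.DataFrame, cfg: dict) -> dict:
    """Run the full analysis on an annotated-or-raw trial log.

    Returns a dict of DataFrames: ``participants``, ``table1``,
    ``compensation``, ``compensation_tests``, ``split_half``.
    """
    target = cfg["target_time"]
    thr = cfg["outlier_sd"]
    conditions = sorted(frame["condition"].unique())
    gain_map = {c: make_gain(c, target=target) for c in conditions}
    boot_entropy = int(np.random.SeedSequence(cfg["seed"]).spawn(2)[1]
                       .generate_state(1)[0])
    boots = {c: _IndexedBootstrap(gain_map[c], cfg, boot_entropy)
             for c in conditions if c in inference.RISK_CONDITIONS}
    shift = cfg["shift_grid"]

    rows = []
    sessions: dict[tuple[str, str], dict] = {}
    for pid, cond, times in _session_arrays(frame):
        g = gain_map[cond]
        mask = trials.filter_outliers(times, thr)
        clean = times[~mask]
        sd = clean.std(ddof=1)
        mean = clean.mean()
        plan = optimal_plan(g, sd)
        emp = inference.empirical_optimum(clean, g, shift["min"], shift["max"],
                                          shift["step"])
        row = {
            "participant_id": pid, "condition": cond,
            "n_trials": times.size, "n_excluded": int(mask.sum()),
            "observed_mean": mean, "observed_sd": sd,
            "optimal_time": plan.optimal_time,
            "optimal_total_gain": cfg["bootstrap"]["n_trials"]
            * plan.optimal_expected_gain,
            "observed_total_gain": float(np.asarray(g(clean)).sum()),
            "empirical_optimal_time": emp.optimal_mean_time,
            "empirical_optimal_shift": emp.optimal_shift,
            "empirical_optimal_total_gain": emp.optimal_total_gain,
        }
        if cond in boots:
            t_opt, lo, hi = boots[cond].at(sd)
            cls = inference.classify_strategy(mean, (lo, hi), cond)
            row.update(ci_lower=lo, ci_upper=hi, ci_t_opt=t_opt,
                       label=cls.label, M=trials.m_statistic(times, target, mask))
        sessions[(pid, cond)] = {"times": times, "mask": mask, "row": row}
        rows.append(row)
    participants = pd.DataFrame(rows)

    # Table-1 analog: per condition, optimal vs observed with paired stats
    table1_rows = []
    for cond in conditions:
        sub = participants[participants["condition"] == cond]
        n = len(sub)
        r = {"condition": cond, "n": n}
        for col, name in (("optimal_time", "optimal_time"),
                          ("observed_mean", "observed_time"),
                          ("optimal_total_gain", "optimal_total_gain"),
                          ("observed_total_gain", "observed_total_gain")):
            r[f"{name}_mean"] = sub[col].mean()
            r[f"{name}_sd"] = sub[col].std(ddof=1) if n > 1 else np.nan
        if n > 1:
            for pair, (a, b) in (
                ("time", ("optimal_time", "observed_mean")),
                ("gain", ("optimal_total_gain", "observed_total_gain")),
            ):
                try:
                    st = trials.paired_stats(sub[a].to_numpy(),
                                             sub[b].to_numpy())
                except ValueError:
                    st = {"t": np.nan, "df": n - 1, "p": np.nan,
                          "cohen_d": np.nan}
                r.update({f"{pair}_{k}": v for k, v in st.items()})
        table1_rows.append(r)
    table1 = pd.DataFrame(table1_rows)

    # Compensation: risk-condition M applied to the paired no-risk session
    risk_conds = [c for c in conditions if c in inference.RISK_CONDITIONS]
    comp_rows = []
    for (pid, cond), sess in sessions.items():
        if cond in risk_conds:
            M = sess["row"]["M"]
        elif cond == "no_risk" and risk_conds:
            key = next(((pid, rc) for rc in risk_conds
                        if (pid, rc) in sessions), None)
            if key is None:
                continue
            M = sessions[key]["row"]["M"]
        else:
            continue
        convention = cfg["bin_convention"] or (
            "exp2" if "risk_before" in risk_conds else "exp1")
        if M <= 0:
            continue
        tab = trials.compensation_table(sess["times"], M, convention,
                                        sess["mask"])
        comp_rows.append({
            "participant_id": pid, "condition": cond, "M": M,
            "convention": convention,
            **{f"{b}_mean": m for b, m in zip(trials.BIN_LABELS, tab.bin_means)},
            **{f"{b}_n": c for b, c in zip(trials.BIN_LABELS, tab.bin_counts)},
        })
    compensation = pd.DataFrame(comp_rows)

    comp_tests = []
    if not compensation.empty and "no_risk" in set(compensation["condition"]):
        for rc in risk_conds:
            a = compensation[compensation["condition"] == rc] \
                .set_index("participant_id")
            b = compensation[compensation["condition"] == "no_risk"] \
                .set_index("participant_id")
            common = a.index.intersection(b.index)
            if len(common) < 2:
                continue
            for bin_label in trials.BIN_LABELS:
                av = a.loc[common, f"{bin_label}_mean"].to_numpy()
                bv = b.loc[common, f"{bin_label}_mean"].to_numpy()
                ok = np.isfinite(av) & np.isfinite(bv)
                if ok.sum() < 2:
                    continue
                try:
                    st = trials.paired_stats(av[ok], bv[ok])
                except ValueError:
                    continue
                comp_tests.append({
                    "comparison": f"{rc}_vs_no_risk", "bin": bin_label,
                    "n": int(ok.sum()),
                    "mean_risk": float(np.mean(av[ok])),
                    "mean_no_risk": float(np.mean(bv[ok])), **st,
                })
    compensation_tests = pd.DataFrame(comp_tests)

    split_rows = []
    for (pid, cond), sess in sessions.items():
        res = trials.split_half_check(sess["times"], sess["mask"])
        split_rows.append({"participant_id": pid, "condition": cond, **res})
    split_half = pd.DataFrame(split_rows)

    return {
        "participants": participants,
        "table1": table1,
        "compensation": compensation,
        "compensation_tests": compensation_tests,
        "split_half": split_half,
    }


def compare_table1(report: dict) -> pd.DataFrame:
    """The optimal-vs-observed condition summary from a report bundle."""
    return report["table1"]


# -------------------------------------------------------------- top level


def run_pipeline(cfg: dict, outdir=None) -> dict:
    """simulate/load -> analyze -> report bundle; optionally write CSVs and
    a manifest under ``outdir``."""
    cfg = resolve_config(cfg if cfg else None) if not _is_resolved(cfg) else cfg
    manifest_agents = None
    if cfg["input"]:
        frame = trials.read_trial_log(cfg["input"])
    else:
        frame, manifest_agents = simulate_from_config(cfg)
    report = analyze(frame, cfg)
    report["trials"] = frame
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("participants", "table1", "compensation",
                     "compensation_tests", "split_half", "trials"):
            report[name].to_csv(outdir / f"{name}.csv", index=False)
        manifest = {"config": cfg, "timeopt_version": __version__,
                    "seed": cfg["seed"]}
        if manifest_agents is not None:
            manifest["agents"] = manifest_agents
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    return report


def _is_resolved(cfg) -> bool:
    return isinstance(cfg, dict) and set(cfg) == set(DEFAULT_CONFIG)
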