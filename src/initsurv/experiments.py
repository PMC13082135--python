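"""Reusable simulation studies: parameter recovery, permutation nulls,
IPTW vs naive contrasts, and sensitivity to weighting choices.

These are the evaluation harnesses the test suite and the reproduction
script both run.  Every study takes an integer seed and is deterministic
given it.  Problem sizes default to desk-scale settings (a few thousand
participants, tens to hundreds of replicates) chosen so a full run completes
in minutes on one CPU; see the methods note for the rationale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize

from .cox import fit_tv_cox
from .msm import (
    compute_stabilized_weights,
    fit_pooled_logistic,
    fit_treatment_models,
    rcs_basis,
)
from .synthetic import ExposureCoefs, SimConfig, _simulate_structural

#: reference treatment-confounder feedback setting: nonzero feedback
#: (kappa) and confounder effect (delta), rare per-interval events, and
#: moderate exposure autocorrelation so an interval-by-interval MSM is a
#: faithful summary of the regime effect.
def reference_config(n: int = 3000, psi: float = float(np.log(2)), seed: int = 0) -> SimConfig:
    return SimConfig(
        n_participants=n,
        psi_true=psi,
        delta_L=0.8,
        kappa_feedback=0.3,
        rho_L=0.5,
        a_coefs=ExposureCoefs(-0.4, 0.6, 0.3, (0.2, 0.1)),
        eta_Z=(0.1, 0.05),
        base_hazard=(-5.3, 0.01),
        extra_outcomes={},
        miss_rate_visit=0.0,
        miss_rate_cell=0.0,
        mc_truth_n=1000,
        seed=seed % 2**31,
    )


def feedback_intervals(cfg: SimConfig, seed: int) -> pd.DataFrame:
    """Exact interval table from one structural simulation (no missingness).

    One row per at-risk person-interval with the exposure and confounder at
    the interval start; events sit on the interval in which they occur.
    """
    n = cfg.n_participants
    sim = _simulate_structural(cfg, n, np.random.default_rng(seed % 2**31))
    vm = sim["visit_months"]
    K = vm.size - 1
    T, ev = sim["outcomes"][cfg.outcome_name]
    frames = []
    for k in range(K):
        ids = np.flatnonzero(T >= vm[k + 1])
        frames.append(pd.DataFrame({
            "id": ids,
            "start": vm[k],
            "stop": vm[k + 1],
            "event_interval": ((T[ids] == vm[k + 1]) & (ev[ids] == 1)).astype(int),
            "expo_a": sim["A"][ids, k].astype(float),
            "conf_l": sim["L"][ids, k],
            "sex": sim["sex"][ids].astype(float),
            "age_z": (sim["age_m"][ids] - 118.9) / 7.4,
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["id", "start"], kind="stable").reset_index(drop=True)


def _msm_one(intervals: pd.DataFrame, clip=0.01, trunc_q=0.99):
    """IPTW and naive pooled-logistic estimates of psi on one interval table."""
    z = ["sex", "age_z"]
    knots = np.unique(np.percentile(intervals["stop"], (5, 35, 65, 95)))
    basis = lambda t: rcs_basis(t, knots=knots)  # noqa: E731
    num, den, *_ = fit_treatment_models(
        intervals, "expo_a", z, ["conf_l"], time_basis=basis
    )
    ws = compute_stabilized_weights(
        num, den, intervals["expo_a"], intervals["id"], clip=clip, trunc_q=trunc_q
    )
    psi_w, se_w, p_w, _ = fit_pooled_logistic(
        intervals, "expo_a", z, weights=ws.weights, time_basis=basis
    )
    psi_n, se_n, p_n, _ = fit_pooled_logistic(
        intervals, "expo_a", z, weights=None, time_basis=basis
    )
    return {
        "psi_iptw": psi_w, "se_iptw": se_w, "p_iptw": p_w,
        "psi_naive": psi_n, "se_naive": se_n, "p_naive": p_n,
        "mean_sw": ws.mean,
    }


def msm_recovery_study(n_reps: int = 100, n: int = 3000, seed: int = 0) -> dict:
    """IPTW vs naive estimation under treatment-confounder feedback.

    Simulates ``n_reps`` cohorts from the reference feedback setting with
    psi = log 2 and rare events, fits the weighted MSM and the naive
    baseline-adjusted pooled logistic on each, and summarizes mean odds
    ratios and absolute biases on the log-odds scale.
    """
    psi_true = float(np.log(2))
    rng = np.random.default_rng(seed % 2**31)
    rows = []
    for _ in range(n_reps):
        s = int(rng.integers(2**31))
        iv = feedback_intervals(reference_config(n=n, psi=psi_true), s)
        rows.append(_msm_one(iv))
    df = pd.DataFrame(rows)
    return {
        "psi_true": psi_true,
        "mean_psi_iptw": float(df["psi_iptw"].mean()),
        "mean_psi_naive": float(df["psi_naive"].mean()),
        "mean_or_iptw": float(np.exp(df["psi_iptw"].mean())),
        "mean_or_naive": float(np.exp(df["psi_naive"].mean())),
        "bias_iptw": float(abs(df["psi_iptw"].mean() - psi_true)),
        "bias_naive": float(abs(df["psi_naive"].mean() - psi_true)),
        "mean_sw": float(df["mean_sw"].mean()),
        "n": n,
        "n_reps": n_reps,
    }


def msm_type1_study(n_reps: int = 200, n: int = 1200, seed: int = 0, alpha: float = 0.05) -> dict:
    """Type-I error of the IPTW MSM under psi = 0 with feedback intact."""
    rng = np.random.default_rng(seed % 2**31)
    rejections = 0
    for _ in range(n_reps):
        s = int(rng.integers(2**31))
        iv = feedback_intervals(reference_config(n=n, psi=0.0), s)
        res = _msm_one(iv)
        rejections += res["p_iptw"] < alpha
    return {"rate": rejections / n_reps, "n_reps": n_reps, "n": n, "alpha": alpha}


def msm_sensitivity_study(
    n: int = 3000, seed: int = 0,
    clips=(0.001, 0.01), trunc_qs=(0.99, 0.995),
) -> pd.DataFrame:
    """psi under each clip x truncation setting on one reference simulation."""
    iv = feedback_intervals(reference_config(n=n), seed)
    rows = []
    for clip in clips:
        for tq in trunc_qs:
            res = _msm_one(iv, clip=clip, trunc_q=tq)
            rows.append({
                "clip": clip, "trunc_q": tq, "psi": res["psi_iptw"],
                "p": res["p_iptw"], "sign": float(np.sign(res["psi_iptw"])),
                "significant": res["p_iptw"] < 0.05,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cox studies

def ph_intervals(n: int, beta: float, seed: int, rate: float = 0.04,
                 censor: float = 48.0, n_cuts: int = 3) -> pd.DataFrame:
    """Continuous-time proportional-hazards data chopped into start-stop rows.

    Exponential event times with hazard ``rate * exp(beta * x)`` for a
    standard-normal time-constant covariate, administratively censored;
    each subject's follow-up is split at equally spaced interior cut points
    (splitting a subject's follow-up must not change the Cox estimate).
    """
    rng = np.random.default_rng(seed % 2**31)
    x = rng.normal(size=n)
    T = rng.exponential(1.0 / (rate * np.exp(beta * x)))
    event = (T <= censor).astype(int)
    T = np.minimum(T, censor)
    rows = []
    for i in range(n):
        cuts = np.linspace(0, T[i], n_cuts + 1)
        for j in range(n_cuts):
            if cuts[j + 1] <= cuts[j]:
                continue
            rows.append((i, cuts[j], cuts[j + 1],
                         event[i] if j == n_cuts - 1 else 0, x[i]))
    return pd.DataFrame(rows, columns=["id", "start", "stop", "event_interval", "x"])


def cox_recovery_study(n_reps: int = 50, n: int = 2000,
                       beta: float = float(np.log(1.5)), seed: int = 0) -> dict:
    """Mean estimate and Monte-Carlo SE across proportional-hazards replicates."""
    rng = np.random.default_rng(seed % 2**31)
    est = []
    for _ in range(n_reps):
        df = ph_intervals(n, beta, int(rng.integers(2**31)))
        fit = fit_tv_cox(df, ["x"])
        est.append(fit.beta[0])
    est = np.asarray(est)
    mc_se = est.std(ddof=1) / np.sqrt(n_reps)
    return {
        "beta_true": beta, "mean_beta": float(est.mean()),
        "mc_se": float(mc_se),
        "z_gap": float(abs(est.mean() - beta) / mc_se),
        "n": n, "n_reps": n_reps,
    }


def permutation_null_study(n_perms: int = 500, n: int = 300, seed: int = 0,
                           alpha: float = 0.05) -> dict:
    """Rejection rate of the cluster-robust Cox test on permuted covariates.

    The covariate is permuted across subjects (breaking any association with
    event times while keeping the marginal distribution), the model is refit
    and the two-sided p-value collected; under the null the alpha-level
    rejection rate should sit inside the binomial sampling band around alpha.
    """
    rng = np.random.default_rng(seed % 2**31)
    df = ph_intervals(n, 0.5, int(rng.integers(2**31)))
    ids = df["id"].to_numpy()
    uid, first = np.unique(ids, return_index=True)
    subj_x = df["x"].to_numpy()[first]
    rejections = 0
    for _ in range(n_perms):
        perm = rng.permutation(subj_x)
        df["x"] = perm[np.searchsorted(uid, ids)]
        fit = fit_tv_cox(df, ["x"])
        rejections += fit["x"].p < alpha
    return {"rate": rejections / n_perms, "n_perms": n_perms, "alpha": alpha}


def bonferroni_fwer_study(n_reps: int = 100, n_predictors: int = 20, n: int = 150,
                          seed: int = 0, alpha: float = 0.05) -> dict:
    """Family-wise error of the Bonferroni-adjusted univariate screen.

    Each replicate screens ``n_predictors`` independent pure-noise columns
    against independently simulated survival data; a replicate counts as a
    family-wise error if any Bonferroni-adjusted p falls below alpha.
    """
    from .cox import screen_univariate

    rng = np.random.default_rng(seed % 2**31)
    fwe = 0
    for _ in range(n_reps):
        df = ph_intervals(n, 0.0, int(rng.integers(2**31)))
        preds = []
        for j in range(n_predictors):
            df[f"p{j}"] = rng.normal(size=len(df))
            preds.append(f"p{j}")
        res = screen_univariate(df, preds, [])
        fwe += bool((res.table["p_bonf"] < alpha).any())
    return {"fwer": fwe / n_reps, "n_reps": n_reps, "n_predictors": n_predictors,
            "alpha": alpha}


# ---------------------------------------------------------------------------
# Brute-force oracle for the Breslow partial likelihood

def naive_breslow_loglik(beta, start, stop, event, X) -> float:
    """Direct risk-set-product evaluation of the Breslow log partial likelihood.

    Written as the literal double loop over event times and intervals (an
    interval [start, stop) is at risk at event time t iff start < t <= stop);
    deliberately independent of the vectorized sweep used by the fitter.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    start = np.asarray(start, float)
    stop = np.asarray(stop, float)
    event = np.asarray(event, int)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != start.size:
        X = X.T
    eta = X @ beta
    ll = 0.0
    for t in np.unique(stop[event == 1]):
        dead = (stop == t) & (event == 1)
        at_risk = (start < t) & (t <= stop)
        ll += eta[dead].sum() - dead.sum() * np.log(np.exp(eta[at_risk]).sum())
    return float(ll)


def brute_force_cox(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    """Numerically maximize the explicit Breslow objective (the oracle)."""
    start = df["start"].to_numpy(float)
    stop = df["stop"].to_numpy(float)
    event = df["event_interval"].to_numpy(int)
    X = df[cols].to_numpy(float)

    def neg(b):
        return -naive_breslow_loglik(b, start, stop, event, X)

    res = optimize.minimize(neg, np.zeros(len(cols)), method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    res = optimize.minimize(neg, res.x, method="Powell",
                            options={"xtol": 1e-12, "ftol": 1e-14})
    return np.asarray(res.x, dtype=float)


def random_tiny_cox_dataset(seed: int, max_subjects: int = 10) -> pd.DataFrame:
    """Small random start-stop dataset with a continuous covariate.

    Designed so the partial likelihood has an interior maximum: several
    events, a continuous covariate, and no separation in expectation.
    """
    rng = np.random.default_rng(seed % 2**31)
    n = int(rng.integers(5, max_subjects + 1))
    rows = []
    for i in range(n):
        t = 0.0
        n_iv = int(rng.integers(1, 4))
        for j in range(n_iv):
            dur = float(rng.uniform(0.5, 6.0))
            ev = int(rng.random() < 0.45) if j == n_iv - 1 else 0
            rows.append((i, t, t + dur, ev, float(rng.normal())))
            t += dur
    df = pd.DataFrame(rows, columns=["id", "start", "stop", "event_interval", "x"])
    if df["event_interval"].sum() < 2:  # keep the likelihood well-behaved
        df.loc[df.index[-1], "event_interval"] = 1
        df.loc[df.index[0], "event_interval"] = 1
    return df


def cox_oracle_study(n_instances: int = 50, seed: int = 0) -> dict:
    """Max |beta_fit - beta_oracle| over random tiny datasets.

    Draws fresh datasets until ``n_instances`` well-posed comparisons have
    been made (toy draws whose likelihood diverges are discarded — the
    brute-force oracle diverges identically on them).
    """
    rng = np.random.default_rng(seed % 2**31)
    worst = 0.0
    compared = 0
    attempts = 0
    while compared < n_instances and attempts < 20 * n_instances:
        attempts += 1
        df = random_tiny_cox_dataset(int(rng.integers(2**31)))
        fit = fit_tv_cox(df, ["x"])
        if not fit.converged or abs(fit.beta[0]) > 5:
            continue
        oracle = brute_force_cox(df, ["x"])
        worst = max(worst, float(abs(fit.beta[0] - oracle[0])))
        compared += 1
    return {"max_abs_gap": worst, "n_instances": compared}
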