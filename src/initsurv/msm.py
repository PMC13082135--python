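"""Marginal structural models with stabilized inverse-probability weights.

For a binary time-varying exposure A_ik the stabilized weight is the
cumulative product over a participant's intervals of

    P(A_im | A_{i,m-1}, Z_i, t_im) / P(A_im | A_{i,m-1}, Z_i, t_im, L_im),

both probabilities estimated by logistic regression (numerator: prior
treatment, baseline covariates, flexible function of time; denominator:
additionally the time-varying confounders).  The causal log-odds ratio psi
comes from a weighted pooled logistic regression of the interval-end event
indicator on a spline basis of time, the current exposure and baseline
covariates, with participant-level cluster-robust standard errors.

Positivity protections follow standard practice: estimated treatment
probabilities are clipped away from 0/1, weights are truncated at an upper
quantile, exposures with extreme prevalence are excluded, and only
exposures passing weight diagnostics (mean near 1, adequate effective
sample size) enter the outcome models and the FDR family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .multiplicity import adjust_bh

logger = logging.getLogger(__name__)

_Z95 = stats.norm.ppf(0.975)


class MsmError(ValueError):
    pass


def dichotomize(values, declared_binary: bool = False) -> np.ndarray:
    """Median split among observed values: 1 if value > median, else 0.

    Already-binary exposures pass through unchanged.
    """
    v = np.asarray(values, dtype=float)
    obs = v[~np.isnan(v)]
    if obs.size == 0:
        raise MsmError("exposure has no observed values")
    if declared_binary or set(np.unique(obs)) <= {0.0, 1.0}:
        return v
    med = np.median(obs)
    out = (v > med).astype(float)
    out[np.isnan(v)] = np.nan
    return out


def rcs_basis(t, knots=None, percentiles=(5, 35, 65, 95)) -> np.ndarray:
    """Restricted (natural) cubic spline basis of time, linear in the tails.

    Knots default to the given percentiles of ``t``.  With fewer than three
    distinct knots the basis degrades gracefully to the linear term alone.
    """
    t = np.asarray(t, dtype=float)
    if knots is None:
        knots = np.unique(np.percentile(t, percentiles))
    knots = np.asarray(sorted(set(np.asarray(knots, float))), dtype=float)
    if knots.size < 3:
        return t[:, None]
    k = knots
    K = k.size
    norm = (k[-1] - k[0]) ** 2

    def tp(x):  # truncated cube
        return np.clip(x, 0, None) ** 3

    cols = [t]
    for j in range(K - 2):
        c = (
            tp(t - k[j])
            - tp(t - k[-2]) * (k[-1] - k[j]) / (k[-1] - k[-2])
            + tp(t - k[-1]) * (k[-2] - k[j]) / (k[-1] - k[-2])
        ) / norm
        cols.append(c)
    return np.column_stack(cols)


def add_prior_exposure(
    intervals: pd.DataFrame, treatment_col: str, id_col: str = "id", start_col: str = "start"
) -> pd.Series:
    """Previous-interval exposure within participant; 0 at the first interval."""
    df = intervals.sort_values([id_col, start_col], kind="stable")
    prev = df.groupby(id_col, sort=False)[treatment_col].shift(1).fillna(0.0)
    return prev.reindex(intervals.index)


def _logit_fit(y, X, label):
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=200)
    except Exception as exc:  # PerfectSeparation and friends
        raise MsmError(f"treatment model for {label} failed: {exc}") from exc
    if not res.converged:
        raise MsmError(f"treatment model for {label} did not converge (separation?)")
    return res


def fit_treatment_models(
    intervals: pd.DataFrame,
    treatment_col: str,
    z_cols: list[str],
    l_cols: list[str],
    *,
    id_col: str = "id",
    stop_col: str = "stop",
    time_basis=None,
):
    """Numerator and denominator treatment-assignment models.

    Returns ``(num_probs, den_probs, num_res, den_res)`` with fitted
    probabilities of the *observed* treatment level P(A=1|...) per interval.
    """
    A = intervals[treatment_col].to_numpy(float)
    if np.isnan(A).any():
        raise MsmError(f"treatment column {treatment_col} contains missing values")
    t = intervals[stop_col].to_numpy(float)
    basis = time_basis(t) if callable(time_basis) else rcs_basis(t)
    prev = add_prior_exposure(intervals, treatment_col, id_col).to_numpy(float)
    ones = np.ones((len(intervals), 1))
    Z = intervals[z_cols].to_numpy(float) if z_cols else np.empty((len(intervals), 0))
    L = intervals[l_cols].to_numpy(float) if l_cols else np.empty((len(intervals), 0))
    X_num = np.hstack([ones, prev[:, None], Z, basis])
    X_den = np.hstack([X_num, L])
    num_res = _logit_fit(A, X_num, f"{treatment_col} (numerator)")
    den_res = _logit_fit(A, X_den, f"{treatment_col} (denominator)")
    return num_res.fittedvalues, den_res.fittedvalues, num_res, den_res


@dataclass
class WeightSet:
    """Stabilized weights per interval with diagnostics."""

    weights: np.ndarray
    mean: float
    max: float
    min: float
    ess_ratio: float
    trunc_q: float
    clip: float
    trunc_value: float

    @classmethod
    def from_weights(cls, w, trunc_q, clip, trunc_value):
        n = w.size
        ess = (w.sum() ** 2) / (n * (w**2).sum()) if n else float("nan")
        return cls(
            weights=w, mean=float(w.mean()), max=float(w.max()), min=float(w.min()),
            ess_ratio=float(ess), trunc_q=trunc_q, clip=clip, trunc_value=float(trunc_value),
        )


def compute_stabilized_weights(
    num_probs,
    den_probs,
    A,
    ids,
    clip: float = 0.01,
    trunc_q: float = 0.99,
) -> WeightSet:
    """Cumulative-product stabilized weights within participant.

    Each interval contributes p if treated else (1-p) for both models;
    probabilities are clipped to [clip, 1-clip] before the ratio; the
    per-interval cumulative products are then truncated (capped) at the
    ``trunc_q`` upper quantile.
    """
    num = np.clip(np.asarray(num_probs, float), clip, 1 - clip)
    den = np.clip(np.asarray(den_probs, float), clip, 1 - clip)
    A = np.asarray(A, float)
    lik_num = np.where(A == 1, num, 1 - num)
    lik_den = np.where(A == 1, den, 1 - den)
    ratio = pd.Series(lik_num / lik_den)
    sw = ratio.groupby(pd.Series(np.asarray(ids)), sort=False).cumprod().to_numpy()
    cap = float(np.quantile(sw, trunc_q)) if sw.size else float("nan")
    return WeightSet.from_weights(np.minimum(sw, cap), trunc_q, clip, cap)


def weight_diagnostics(
    ws: WeightSet,
    prevalence: float,
    p_lo: float = 0.05,
    p_hi: float = 0.95,
    mean_lo: float = 0.9,
    mean_hi: float = 1.1,
    ess_min: float = 0.5,
) -> tuple[bool, dict]:
    """Predefined weight-quality criteria; failures exclude the exposure."""
    reasons = []
    if not p_lo <= prevalence <= p_hi:
        reasons.append(f"prevalence {prevalence:.3f} outside [{p_lo}, {p_hi}]")
    if not mean_lo <= ws.mean <= mean_hi:
        reasons.append(f"mean weight {ws.mean:.3f} outside [{mean_lo}, {mean_hi}]")
    if ws.ess_ratio < ess_min:
        reasons.append(f"ESS ratio {ws.ess_ratio:.3f} < {ess_min}")
    report = {
        "prevalence": prevalence, "mean_w": ws.mean, "max_w": ws.max,
        "min_w": ws.min, "ess_ratio": ws.ess_ratio, "reasons": reasons,
    }
    return (not reasons), report


@dataclass
class MSMResult:
    exposure: str
    psi: float = float("nan")
    or_: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p: float = float("nan")
    q: float = float("nan")
    retained: bool = False
    reason: str = ""
    weight_report: dict = field(default_factory=dict)


def fit_pooled_logistic(
    intervals: pd.DataFrame,
    treatment_col: str,
    z_cols: list[str],
    weights=None,
    *,
    id_col: str = "id",
    stop_col: str = "stop",
    event_col: str = "event_interval",
    time_basis=None,
):
    """(Weighted) pooled logistic regression of the interval-end event.

    Uses GEE with an independence working correlation so standard errors are
    participant-level cluster-robust; ``weights=None`` gives the unweighted
    (naive) fit.  Returns ``(psi, se, p, result)`` for the treatment term.
    """
    y = intervals[event_col].to_numpy(float)
    t = intervals[stop_col].to_numpy(float)
    basis = time_basis(t) if callable(time_basis) else rcs_basis(t)
    Z = intervals[z_cols].to_numpy(float) if z_cols else np.empty((len(intervals), 0))
    A = intervals[treatment_col].to_numpy(float)
    X = np.hstack([np.ones((len(intervals), 1)), basis, A[:, None], Z])
    names = (["const"] + [f"t{j}" for j in range(basis.shape[1])] + ["treat"]
             + list(z_cols))
    Xdf = pd.DataFrame(X, columns=names)
    groups = intervals[id_col].to_numpy()
    model = sm.GEE(
        y, Xdf, groups=groups, family=sm.families.Binomial(),
        cov_struct=sm.cov_struct.Independence(),
        weights=None if weights is None else np.asarray(weights, float),
    )
    res = model.fit(maxiter=100)
    psi = float(res.params["treat"])
    se = float(res.bse["treat"])
    p = float(res.pvalues["treat"])
    return psi, se, p, res


def fit_msm(
    intervals: pd.DataFrame,
    treatment_col: str,
    z_cols: list[str],
    weights: WeightSet,
    *,
    time_basis=None,
    **kw,
) -> MSMResult:
    """Weighted pooled logistic MSM for one exposure (diagnostics passed)."""
    try:
        psi, se, p, _ = fit_pooled_logistic(
            intervals, treatment_col, z_cols, weights=weights.weights,
            time_basis=time_basis, **kw,
        )
    except Exception as exc:
        logger.warning("fit_msm: %s failed: %s", treatment_col, exc)
        return MSMResult(exposure=treatment_col, retained=False, reason=str(exc))
    return MSMResult(
        exposure=treatment_col,
        psi=psi,
        or_=float(np.exp(psi)),
        ci_low=float(np.exp(psi - _Z95 * se)),
        ci_high=float(np.exp(psi + _Z95 * se)),
        p=p,
        retained=True,
    )


def fdr_across_exposures(results: list[MSMResult]) -> list[MSMResult]:
    """BH q-values over the retained family only."""
    retained = [r for r in results if r.retained]
    if retained:
        qs = adjust_bh([r.p for r in retained])
        for r, q in zip(retained, qs):
            r.q = float(q)
    return results


def run_msm(
    intervals: pd.DataFrame,
    exposures: dict[str, dict],
    z_cols: list[str],
    *,
    clip: float = 0.01,
    trunc_q: float = 0.99,
    p_lo: float = 0.05,
    p_hi: float = 0.95,
    mean_lo: float = 0.9,
    mean_hi: float = 1.1,
    ess_min: float = 0.5,
    id_col: str = "id",
    stop_col: str = "stop",
    event_col: str = "event_interval",
) -> list[MSMResult]:
    """Full per-exposure IPTW analysis with diagnostics and FDR control.

    ``exposures`` maps exposure name to a dict with keys ``column`` (source
    column), ``binary`` (bool), and ``confounders`` (denominator L columns).
    """
    knots = np.unique(np.percentile(intervals[stop_col].to_numpy(float), (5, 35, 65, 95)))
    basis = lambda t: rcs_basis(t, knots=knots)  # noqa: E731
    results = []
    for name, spec in exposures.items():
        col = spec.get("column", name)
        work = intervals.copy()
        try:
            work["_treat"] = dichotomize(work[col], spec.get("binary", False))
        except MsmError as exc:
            results.append(MSMResult(exposure=name, retained=False, reason=str(exc)))
            continue
        prevalence = float(np.nanmean(work["_treat"]))
        if not p_lo <= prevalence <= p_hi:
            results.append(MSMResult(
                exposure=name, retained=False,
                reason=f"prevalence {prevalence:.3f} outside [{p_lo}, {p_hi}]",
                weight_report={"prevalence": prevalence},
            ))
            continue
        l_cols = [c for c in spec.get("confounders", []) if c in work.columns]
        try:
            num_p, den_p, *_ = fit_treatment_models(
                work, "_treat", z_cols, l_cols, id_col=id_col, stop_col=stop_col,
                time_basis=basis,
            )
        except MsmError as exc:
            results.append(MSMResult(exposure=name, retained=False, reason=str(exc)))
            continue
        ws = compute_stabilized_weights(
            num_p, den_p, work["_treat"], work[id_col], clip=clip, trunc_q=trunc_q
        )
        ok, report = weight_diagnostics(
            ws, prevalence, p_lo, p_hi, mean_lo, mean_hi, ess_min
        )
        if not ok:
            results.append(MSMResult(
                exposure=name, retained=False,
                reason="; ".join(report["reasons"]), weight_report=report,
            ))
            continue
        res = fit_msm(
            work, "_treat", z_cols, ws, time_basis=basis,
            id_col=id_col, stop_col=stop_col, event_col=event_col,
        )
        res.exposure = name
        res.weight_report = report
        results.append(res)
    return fdr_across_exposures(results)


def results_frame(results: list[MSMResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "exposure": r.exposure, "psi": r.psi, "OR": r.or_,
            "CI_low": r.ci_low, "CI_high": r.ci_high, "p": r.p, "q": r.q,
            "mean_w": r.weight_report.get("mean_w", float("nan")),
            "max_w": r.weight_report.get("max_w", float("nan")),
            "ess_ratio": r.weight_report.get("ess_ratio", float("nan")),
            "retained": r.retained, "reason": r.reason,
        }
        for r in results
    ])
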