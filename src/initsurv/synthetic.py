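"""Synthetic longitudinal cohort generator with known causal structure.

Emulates an ABCD-like adolescent cohort: a ~4-year visit schedule with
annual assessments and mid-year phone contacts (months 0, 6, ..., 48),
baseline covariates (sex, baseline age in months, study site, ancestry PCs,
polygenic scores), a time-varying confounder with AR(1) dynamics and
exposure feedback, a binary time-varying exposure, per-substance
first-endorsement items, MCAR missingness, and discrete-time initiation
events.  Because every structural coefficient is known, the generator
doubles as ground truth for parameter-recovery tests: ``SimTruth`` carries
the causal log-odds ratio ``psi`` and a Monte-Carlo counterfactual marginal
odds ratio computed by re-simulating the cohort under do(A=1) vs do(A=0).

The discrete-time event model is
``logit P(Y_ik = 1) = alpha0 + alpha1 * t_k + psi * A_ik + delta * L_ik + eta' Z_i``
with per-interval probabilities kept small by default so that the marginal
odds ratio is close to ``exp(psi)`` (rare-event collapsibility).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


#: visit labels for the default schedule (annual + mid-year phone contacts)
def visit_labels(visit_months) -> list[str]:
    labels = []
    for m in visit_months:
        if m == 0:
            labels.append("baseline")
        elif m % 12 == 0:
            labels.append(f"fu{m // 12}")
        else:
            labels.append(f"phone_{m:02d}")
    return labels


@dataclass
class ExposureCoefs:
    """Coefficients of the logistic exposure (treatment-assignment) model."""

    intercept: float = -0.4
    confounder: float = 0.8
    prior_exposure: float = 0.8
    baseline: tuple[float, ...] = (0.2, 0.1)  # (sex, standardized baseline age)


@dataclass
class SimConfig:
    n_participants: int = 500
    visit_months: tuple[int, ...] = (0, 6, 12, 18, 24, 30, 36, 42, 48)
    n_sites: int = 5
    n_pcs: int = 20
    n_prs: int = 4
    rho_L: float = 0.5
    kappa_feedback: float = 0.5
    a_coefs: ExposureCoefs = field(default_factory=ExposureCoefs)
    psi_true: float = float(np.log(2.0))
    delta_L: float = 0.7
    eta_Z: tuple[float, ...] = (0.1, 0.05)
    #: (logit intercept, per-month slope) of the baseline event hazard for the
    #: primary outcome; the default targets ~36.5% cumulative incidence.
    base_hazard: tuple[float, float] = (-4.392, 0.015)
    #: additional outcomes simulated from the same structural model with their
    #: own baseline hazard; the default targets ~5.4% cumulative incidence.
    extra_outcomes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"nicotine_like": (-6.602, 0.015)}
    )
    outcome_name: str = "alcohol_like"
    n_noise_predictors: int = 5
    religious_flag_rate: float = 0.0
    miss_rate_visit: float = 0.1
    miss_rate_cell: float = 0.1
    monotone_dropout: bool = False
    mc_truth_n: int = 100_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        vm = list(self.visit_months)
        if not vm or vm[0] != 0 or any(b <= a for a, b in zip(vm, vm[1:])):
            raise ConfigError("visit_months must be strictly increasing and start at 0")
        for name in ("miss_rate_visit", "miss_rate_cell", "religious_flag_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        for name in ("n_sites", "n_pcs", "n_prs"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if len(self.eta_Z) != len(self.a_coefs.baseline):
            raise ConfigError("eta_Z must match a_coefs.baseline in length")


@dataclass
class SimTruth:
    psi_true: float
    marginal_or_mc: float
    cumulative_incidence: dict[str, float]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def simulate_exposure_history(L_path, Z, a_coefs: ExposureCoefs, rng) -> np.ndarray:
    """Binary exposure sequences with dependence on the confounder and on
    the previous interval's exposure (history initialized to 0).

    ``L_path`` is (n, K); ``Z`` is (n, d) baseline covariates.
    """
    L_path = np.atleast_2d(np.asarray(L_path, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != L_path.shape[0]:
        raise ValueError("dimension mismatch between L_path and Z")
    b = np.asarray(a_coefs.baseline, dtype=float)
    if Z.shape[1] != b.size:
        raise ValueError("dimension mismatch between Z and a_coefs.baseline")
    n, K = L_path.shape
    A = np.zeros((n, K), dtype=int)
    prev = np.zeros(n)
    zterm = Z @ b
    for k in range(K):
        p = expit(a_coefs.intercept + a_coefs.confounder * L_path[:, k]
                  + a_coefs.prior_exposure * prev + zterm)
        A[:, k] = rng.random(n) < p
        prev = A[:, k]
    return A


def simulate_events(A, L, Z, psi, delta_L, eta_Z, base_hazard, times, rng):
    """Discrete-time initiation events over aligned interval sequences.

    Per interval k (ending at ``times[k]`` months) the event indicator is
    Bernoulli with logit ``alpha0 + alpha1*t_k + psi*A_k + delta*L_k + eta'Z``;
    the first success sets the follow-up time T to that interval's end,
    otherwise the participant is censored at the last visit.
    Returns (T, event) arrays.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    L = np.atleast_2d(np.asarray(L, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if A.shape != L.shape:
        raise ValueError("A and L must have matching shapes")
    n, K = A.shape
    times = np.asarray(times, dtype=float)
    if times.size != K:
        raise ValueError("times must have one entry per interval")
    alpha0, alpha1 = base_hazard
    zterm = Z @ np.asarray(eta_Z, dtype=float)
    T = np.full(n, times[-1])
    event = np.zeros(n, dtype=int)
    alive = np.ones(n, dtype=bool)
    for k in range(K):
        logit = alpha0 + alpha1 * times[k] + psi * A[:, k] + delta_L * L[:, k] + zterm
        y = (rng.random(n) < expit(logit)) & alive
        T[y] = times[k]
        event[y] = 1
        alive &= ~y
    return T, event


def _simulate_structural(cfg: SimConfig, n: int, rng, forced_A=None):
    """Core structural simulation shared by the factual and counterfactual runs.

    Returns dict with baseline covariates, L (n, K) at interval starts,
    A (n, K), and per-outcome (T, event).
    """
    vm = np.asarray(cfg.visit_months, dtype=float)
    K = vm.size - 1  # intervals
    sex = (rng.random(n) < 0.5).astype(int)
    age_m = rng.normal(118.9, 7.4, size=n)
    site = rng.integers(0, cfg.n_sites, size=n)
    pcs = rng.normal(size=(n, cfg.n_pcs))
    prs = rng.normal(size=(n, cfg.n_prs))
    Z = np.column_stack([sex, (age_m - 118.9) / 7.4])

    # confounder at each interval start (visits 0..K-1), AR(1) + feedback
    innov_sd = np.sqrt(max(1.0 - cfg.rho_L**2, 1e-12))
    L = np.zeros((n, K))
    A = np.zeros((n, K), dtype=int)
    b = np.asarray(cfg.a_coefs.baseline, dtype=float)
    zterm_a = Z @ b
    prev_A = np.zeros(n)
    for k in range(K):
        if k == 0:
            L[:, 0] = rng.normal(size=n)
        else:
            L[:, k] = (cfg.rho_L * L[:, k - 1] + cfg.kappa_feedback * prev_A
                       + rng.normal(scale=innov_sd, size=n))
        if forced_A is None:
            p = expit(cfg.a_coefs.intercept + cfg.a_coefs.confounder * L[:, k]
                      + cfg.a_coefs.prior_exposure * prev_A + zterm_a)
            A[:, k] = rng.random(n) < p
        else:
            A[:, k] = forced_A
        prev_A = A[:, k]

    hazards = {cfg.outcome_name: cfg.base_hazard, **cfg.extra_outcomes}
    outcomes = {}
    for name, bh in hazards.items():
        T, event = simulate_events(
            A, L, Z, cfg.psi_true, cfg.delta_L, cfg.eta_Z, bh, vm[1:], rng
        )
        outcomes[name] = (T, event)
    return {
        "sex": sex, "age_m": age_m, "site": site, "pcs": pcs, "prs": prs,
        "Z": Z, "L": L, "A": A, "outcomes": outcomes, "visit_months": vm,
    }


def _counterfactual_marginal_or(cfg: SimConfig) -> float:
    """Pooled person-interval odds ratio under do(A=1) vs do(A=0)."""
    rng1 = np.random.default_rng((cfg.seed + 1) % 2**31)
    n = cfg.mc_truth_n
    odds = {}
    for a in (1, 0):
        sim = _simulate_structural(cfg, n, np.random.default_rng(rng1.integers(2**31)),
                                   forced_A=a)
        T, event = sim["outcomes"][cfg.outcome_name]
        vm = sim["visit_months"]
        # person-intervals at risk: intervals ending at vm[1:] with end <= T
        n_intervals = np.searchsorted(vm[1:], T, side="right").sum()
        n_events = event.sum()
        odds[a] = n_events / max(n_intervals - n_events, 1)
    return float(odds[1] / odds[0]) if odds[0] > 0 else float("inf")


def generate_cohort(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate (LongTable, BaselineTable, SimTruth) for one synthetic cohort.

    The long table has one row per retained participant-visit with the
    confounder, the exposure, noise predictors, and per-outcome endorsement
    items (1 from the first post-initiation visit onward); missingness is
    MCAR at the visit level (whole follow-up contact dropped; baseline always
    retained) and at the cell level.  Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed % 2**31)
    n = cfg.n_participants
    sim = _simulate_structural(cfg, n, rng)
    vm = sim["visit_months"]
    n_visits = vm.size

    baseline = pd.DataFrame({
        "id": np.arange(n),
        "sex": sim["sex"],
        "baseline_age_months": sim["age_m"],
        "site": sim["site"],
    })
    for j in range(cfg.n_pcs):
        baseline[f"pc{j + 1}"] = sim["pcs"][:, j]
    for j in range(cfg.n_prs):
        baseline[f"prs_{j + 1}"] = sim["prs"][:, j]

    labels = visit_labels(cfg.visit_months)
    # noise predictors: iid standard normal per visit
    aux = rng.normal(size=(n, n_visits, cfg.n_noise_predictors))

    # visit-level MCAR dropout (baseline always kept)
    keep = rng.random((n, n_visits)) >= cfg.miss_rate_visit
    keep[:, 0] = True
    if cfg.monotone_dropout:
        keep = np.logical_and.accumulate(keep, axis=1)

    rows = []
    outcome_names = list(sim["outcomes"])
    religious = {}
    if cfg.religious_flag_rate > 0:
        for name in outcome_names:
            religious[name] = rng.random((n, n_visits)) < cfg.religious_flag_rate
    cell_miss = rng.random((n, n_visits, 1 + cfg.n_noise_predictors + len(outcome_names)))
    for v in range(n_visits):
        month = vm[v]
        mask = keep[:, v]
        ids = np.flatnonzero(mask)
        rec = {
            "id": ids,
            "visit": labels[v],
            "interview_age_months": sim["age_m"][ids] + month,
        }
        # confounder at visit v (defined at interval starts; last visit carries NA)
        Lv = sim["L"][ids, v] if v < vm.size - 1 else np.full(ids.size, np.nan)
        Lv = np.where(cell_miss[ids, v, 0] < cfg.miss_rate_cell, np.nan, Lv)
        rec["conf_l"] = Lv
        Av = sim["A"][ids, v] if v < vm.size - 1 else np.full(ids.size, np.nan)
        rec["expo_a"] = Av
        for j in range(cfg.n_noise_predictors):
            col = aux[ids, v, j]
            col = np.where(cell_miss[ids, v, 1 + j] < cfg.miss_rate_cell, np.nan, col)
            rec[f"aux{j + 1}"] = col
        for oi, name in enumerate(outcome_names):
            T, event = sim["outcomes"][name]
            item = ((event[ids] == 1) & (vm[v] >= T[ids]) & (vm[v] > 0)).astype(float)
            miss = cell_miss[ids, v, 1 + cfg.n_noise_predictors + oi] < cfg.miss_rate_cell
            item = np.where(miss, np.nan, item)
            rec[f"{name}_item"] = item
            if name in religious:
                rec[f"{name}_religious_flag"] = religious[name][ids, v].astype(int)
        rows.append(pd.DataFrame(rec))
    long_table = pd.concat(rows, ignore_index=True)
    order = {lab: i for i, lab in enumerate(labels)}
    long_table = long_table.sort_values(
        ["id", "visit"], key=lambda s: s.map(order) if s.name == "visit" else s,
        kind="stable",
    ).reset_index(drop=True)

    cum_inc = {
        name: float(ev.mean()) for name, (T, ev) in sim["outcomes"].items()
    }
    truth = SimTruth(
        psi_true=cfg.psi_true,
        marginal_or_mc=_counterfactual_marginal_or(cfg),
        cumulative_incidence=cum_inc,
    )
    return long_table, baseline, truth


def write_cohort(long_table: pd.DataFrame, baseline: pd.DataFrame, truth: SimTruth,
                 outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    long_table.to_csv(outdir / "long_table.csv", index=False)
    baseline.to_csv(outdir / "baseline.csv", index=False)
    truth.to_json(outdir / "sim_truth.json")
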