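"""End-to-end orchestration: simulate -> outcomes -> intervals -> QC ->
screen -> multivariable Cox -> MSM, with deterministic seeding, TSV outputs
and a JSON manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cox import MultivarSpec, fit_multivariable, prescreen, screen_univariate
from .intervals import build_interval_table, compute_time_months, encode_value_availability, forward_fill
from .lasso import lasso_screen
from .msm import results_frame, run_msm
from .outcomes import OutcomeSpec, derive_outcome, harmonize_sources, mask_religious_context
from .qc import coverage_fraction, run_qc
from .synthetic import SimConfig, generate_cohort, visit_labels, write_cohort

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class QCSettings:
    freq_threshold: float = 0.99
    r_threshold: float = 0.9
    min_coverage: float = 0.5


@dataclass
class CoxSettings:
    p_enter: float = 0.05
    k_folds: int = 10
    univariate_site: str = "fixed"  # "fixed" indicators or "strata"


@dataclass
class MSMSettings:
    clip: float = 0.01
    trunc_q: float = 0.99
    p_lo: float = 0.05
    p_hi: float = 0.95
    mean_lo: float = 0.9
    mean_hi: float = 1.1
    ess_min: float = 0.5
    exposures: dict = field(default_factory=lambda: {
        "expo_a": {"column": "expo_a", "binary": True, "confounders": ["conf_l"]},
    })


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run_out"
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QCSettings = field(default_factory=QCSettings)
    cox: CoxSettings = field(default_factory=CoxSettings)
    msm: MSMSettings = field(default_factory=MSMSettings)
    domain_map: dict = field(default_factory=lambda: {
        "conf_l": "family", "expo_a": "behavior",
    })

    _NESTED = {"sim": SimConfig, "qc": QCSettings, "cox": CoxSettings, "msm": MSMSettings}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, data, path):
            if not isinstance(data, dict):
                raise ConfigError(f"{path}: expected a mapping")
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(data) - names
            if unknown:
                raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
            kwargs = {}
            for k, v in data.items():
                if klass is cls and k in cls._NESTED:
                    kwargs[k] = build(cls._NESTED[k], v, f"{path}.{k}")
                elif isinstance(v, list) and k in ("visit_months", "eta_Z", "baseline"):
                    kwargs[k] = tuple(v)
                else:
                    kwargs[k] = v
            return klass(**kwargs)

        return build(cls, d, "config")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def render_domain_summary(screen_table: pd.DataFrame, domain_map: dict) -> pd.DataFrame:
    """Per-domain counts of FDR-significant and Bonferroni-significant hits."""
    if screen_table.empty:
        return pd.DataFrame(columns=["domain", "n_fdr", "n_bonferroni"])
    df = screen_table.copy()
    if "domain" not in df.columns:
        df["domain"] = [domain_map.get(p, "other") for p in df["predictor"]]
    df["domain"] = df["domain"].fillna("other")
    agg = df.groupby("domain").agg(
        n_fdr=("q", lambda s: int((s < 0.05).sum())),
        n_bonferroni=("p_bonf", lambda s: int((s < 0.05).sum())),
    ).reset_index()
    return agg


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage and write results under ``cfg.out_dir``.

    Identical config + seed yields byte-identical outputs (and therefore
    identical manifest hashes).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("initsurv")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    t0 = time.time()
    stage = "simulate"
    try:
        sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed % 2**31)
        long_table, baseline, truth = generate_cohort(sim_cfg)
        write_cohort(long_table, baseline, truth, out)

        stage = "derive-outcomes"
        labels = visit_labels(sim_cfg.visit_months)
        outcome_names = [sim_cfg.outcome_name, *sim_cfg.extra_outcomes]
        item_cols = [f"{n}_item" for n in outcome_names]
        harmonized = harmonize_sources(long_table, None, item_cols, visit_order=labels)
        outcome_frames = {}
        for name in outcome_names:
            spec = OutcomeSpec(
                name=name, items=[f"{name}_item"],
                religious_flags=(
                    {f"{name}_item": f"{name}_religious_flag"}
                    if f"{name}_religious_flag" in harmonized.columns else {}
                ),
                censor_visit=labels[-1], control_visit=labels[-3],
            )
            masked = mask_religious_context(harmonized, spec)
            outcome_frames[name] = derive_outcome(masked, spec, visit_order=labels)
        outcomes_tsv = pd.concat(
            [df.assign(outcome=name) for name, df in outcome_frames.items()]
        )
        outcomes_tsv.to_csv(out / "outcomes.tsv", sep="\t", index=False)

        stage = "build-intervals"
        merged = long_table.merge(
            baseline[["id", "baseline_age_months"]], on="id", how="left"
        )
        merged["time"] = [
            compute_time_months(a, b)
            for a, b in zip(merged["interview_age_months"], merged["baseline_age_months"])
        ]
        predictors = ["conf_l", *(c for c in long_table.columns if c.startswith("aux"))]

        stage = "qc"
        _, kept_predictors, qc_report = run_qc(
            merged, predictors,
            freq_threshold=cfg.qc.freq_threshold, r_threshold=cfg.qc.r_threshold,
            min_coverage=cfg.qc.min_coverage,
        )
        qc_report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        coverage = coverage_fraction(merged, kept_predictors)

        filled = forward_fill(merged, kept_predictors + ["expo_a"])
        encoded, kept_predictors = encode_value_availability(filled, kept_predictors)
        encoded["expo_a"] = encoded["expo_a"].fillna(0.0)
        baseline_cols = ["sex", "baseline_age_months", "site"] + \
            [c for c in baseline.columns if c.startswith(("pc", "prs_"))]
        encoded = encoded.merge(
            baseline.drop(columns=["baseline_age_months"]), on="id", how="left"
        )
        site_dummies = pd.get_dummies(encoded["site"], prefix="site", drop_first=True).astype(float)
        encoded = pd.concat([encoded, site_dummies], axis=1)
        covariate_cols = (
            kept_predictors + [c + "_obs" for c in kept_predictors] + ["expo_a"]
            + baseline_cols + list(site_dummies.columns)
        )
        forced = ["sex", "baseline_age_months"] + [c for c in baseline.columns if c.startswith("pc")]
        prs_cols = [c for c in baseline.columns if c.startswith("prs_")]

        manifest_models = {}
        for name in outcome_names:
            stage = f"build-intervals[{name}]"
            odf = outcome_frames[name]
            usable = odf[odf["T"] > 0]
            ivs = build_interval_table(encoded, usable, covariate_cols)

            stage = f"screen[{name}]"
            candidates = kept_predictors + ["expo_a"] + prs_cols
            screen_forced = forced + (
                list(site_dummies.columns) if cfg.cox.univariate_site == "fixed" else []
            )
            screen_strata = None if cfg.cox.univariate_site == "fixed" else "site"
            screen = screen_univariate(
                ivs, candidates, screen_forced, strata_col=screen_strata,
                domain_map=cfg.domain_map,
            )
            screen.table.to_csv(out / f"screen_{name}.tsv", sep="\t", index=False)
            render_domain_summary(screen.table, cfg.domain_map).to_csv(
                out / f"domain_summary_{name}.tsv", sep="\t", index=False
            )

            stage = f"select[{name}]"
            coverage_all = dict(coverage, **{c: 1.0 for c in ["expo_a", *prs_cols]})
            pre = prescreen(screen, coverage_all, cfg.cox.p_enter, cfg.qc.min_coverage)
            selected = lasso_screen(
                ivs, pre, forced, k_folds=cfg.cox.k_folds,
                seed=(cfg.seed + 101) % 2**31,
            ) if pre else []

            stage = f"fit-multivariable[{name}]"
            spec = MultivarSpec(
                forced_cols=forced, strata_col="site", selected=selected,
                availability_cols=[c + "_obs" for c in selected
                                   if c + "_obs" in ivs.columns],
            )
            multi = fit_multivariable(ivs, spec, domain_map=cfg.domain_map)
            multi.full_table.to_csv(out / f"multivar_{name}.tsv", sep="\t", index=False)

            stage = f"msm[{name}]"
            msm_results = run_msm(
                ivs, cfg.msm.exposures, forced,
                clip=cfg.msm.clip, trunc_q=cfg.msm.trunc_q,
                p_lo=cfg.msm.p_lo, p_hi=cfg.msm.p_hi,
                mean_lo=cfg.msm.mean_lo, mean_hi=cfg.msm.mean_hi,
                ess_min=cfg.msm.ess_min,
            )
            results_frame(msm_results).to_csv(out / f"msm_{name}.tsv", sep="\t", index=False)
            manifest_models[name] = {
                "n_intervals": int(len(ivs)),
                "n_events": int(ivs["event_interval"].sum()),
                "selected": selected,
            }
    except Exception:
        logger.exception("pipeline failed at stage %s", stage)
        root.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline failed at stage {stage!r}; see {log_path}") from None
    finally:
        if handler in root.handlers:
            root.removeHandler(handler)
            handler.close()

    manifest = {
        "package": "initsurv",
        "version": __version__,
        "seed": cfg.seed,
        "elapsed_s": round(time.time() - t0, 2),
        "settings": {
            "qc": dataclasses.asdict(cfg.qc),
            "cox": dataclasses.asdict(cfg.cox),
            "msm": dataclasses.asdict(cfg.msm),
        },
        "models": manifest_models,
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.suffix in {".tsv", ".csv", ".json"} and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
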