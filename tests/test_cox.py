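"""Time-varying Cox fitter: oracle equivalence, sandwich variance, screening."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from initsurv import fit_tv_cox, screen_univariate, prescreen
from initsurv.cox import CoxError, MultivarSpec, ScreenResult, fit_multivariable
from initsurv.experiments import brute_force_cox, naive_breslow_loglik
from initsurv.multiplicity import adjust_bh, adjust_bonferroni


class TestAgainstBruteForce:
    def test_six_subject_toy_matches_explicit_partial_likelihood(self):
        # 6 subjects, 3 events, one binary covariate
        df = pd.DataFrame({
            "id": range(6),
            "start": [0.0] * 6,
            "stop": [2.0, 3.0, 4.0, 5.0, 6.0, 7.0],
            "event_interval": [1, 0, 1, 0, 1, 0],
            "x": [1.0, 1.0, 0.0, 0.0, 1.0, 0.0],
        })
        fit = fit_tv_cox(df, ["x"])
        oracle = brute_force_cox(df, ["x"])
        assert fit.beta[0] == pytest.approx(oracle[0], abs=1e-6)
        # the fitted point is a maximum of the explicitly coded objective
        args = (df["start"], df["stop"], df["event_interval"], df[["x"]])
        ll_hat = naive_breslow_loglik(fit.beta, *args)
        for d in (-1e-3, 1e-3):
            assert ll_hat >= naive_breslow_loglik(fit.beta + d, *args)

    def test_startstop_data_matches_brute_force(self, startstop_df):
        fit = fit_tv_cox(startstop_df, ["x1", "x2"])
        oracle = brute_force_cox(startstop_df, ["x1", "x2"])
        assert np.allclose(fit.beta, oracle, atol=1e-6)


@pytest.mark.parametrize("strata", [None, "site"])
def test_matches_r_survival_coxph(tmp_path, startstop_df, strata):
    """Cross-check beta and cluster-robust SE against survival::coxph."""
    df = startstop_df.copy()
    df["site"] = df["id"] % 3
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    strata_term = "+ strata(site)" if strata else ""
    script = f"""
    suppressMessages(library(survival))
    df <- read.csv("{csv}")
    f <- coxph(Surv(start, stop, event_interval) ~ x1 + x2 {strata_term} + cluster(id),
               data = df, ties = "breslow")
    cat(sprintf("%.10f ", c(coef(f), sqrt(diag(vcov(f))))))
    """
    out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, check=True)
    vals = np.array([float(v) for v in out.stdout.split()])
    fit = fit_tv_cox(df, ["x1", "x2"], strata_col=strata)
    assert np.allclose(fit.beta, vals[:2], atol=1e-6)
    assert np.allclose(np.sqrt(np.diag(fit.cov_robust)), vals[2:], atol=1e-6)


class TestSandwich:
    def test_cloning_subjects_with_shared_cluster_preserves_robust_se(self, startstop_df):
        fit = fit_tv_cox(startstop_df, ["x1"])
        clones = startstop_df.copy()
        clones["id"] = clones["id"] + 10_000
        doubled_distinct = pd.concat([startstop_df, clones], ignore_index=True)
        doubled_shared = pd.concat([startstop_df, startstop_df], ignore_index=True)

        fit_distinct = fit_tv_cox(doubled_distinct, ["x1"])
        fit_shared = fit_tv_cox(doubled_shared, ["x1"])
        se = np.sqrt(fit.cov_robust[0, 0])
        assert fit_distinct.beta[0] == pytest.approx(fit.beta[0], abs=1e-8)
        assert fit_shared.beta[0] == pytest.approx(fit.beta[0], abs=1e-8)
        # distinct clones: information doubles, robust SE shrinks ~ 1/sqrt(2)
        assert np.sqrt(fit_distinct.cov_robust[0, 0]) == pytest.approx(se / np.sqrt(2), rel=1e-6)
        # shared cluster ids: the sandwich cancels the duplication exactly
        assert np.sqrt(fit_shared.cov_robust[0, 0]) == pytest.approx(se, rel=1e-9)

    def test_naive_se_shrinks_under_duplication(self, startstop_df):
        fit = fit_tv_cox(startstop_df, ["x1"])
        doubled = pd.concat([startstop_df, startstop_df], ignore_index=True)
        fit2 = fit_tv_cox(doubled, ["x1"])
        assert np.sqrt(fit2.cov_naive[0, 0]) < np.sqrt(fit.cov_naive[0, 0])


class TestInvariances:
    def test_time_shift_leaves_beta_unchanged(self, startstop_df):
        fit = fit_tv_cox(startstop_df, ["x1", "x2"])
        shifted = startstop_df.assign(start=startstop_df["start"] + 7.5,
                                      stop=startstop_df["stop"] + 7.5)
        fit2 = fit_tv_cox(shifted, ["x1", "x2"])
        assert np.allclose(fit.beta, fit2.beta, atol=1e-8)

    def test_covariate_scaling_scales_beta_inversely(self, startstop_df):
        fit = fit_tv_cox(startstop_df, ["x1"])
        scaled = startstop_df.assign(x1=startstop_df["x1"] * 4.0)
        fit2 = fit_tv_cox(scaled, ["x1"])
        assert fit2.beta[0] == pytest.approx(fit.beta[0] / 4.0, rel=1e-6)


class TestErrors:
    def test_zero_events_rejected(self, startstop_df):
        df = startstop_df.assign(event_interval=0)
        with pytest.raises(CoxError, match="zero events"):
            fit_tv_cox(df, ["x1"])

    def test_constant_column_named(self, startstop_df):
        df = startstop_df.assign(flat=1.0)
        with pytest.raises(CoxError, match="flat"):
            fit_tv_cox(df, ["flat"])

    def test_separation_flagged_not_silent(self):
        # covariate perfectly orders event vs censored subjects -> monotone likelihood
        df = pd.DataFrame({
            "id": range(8), "start": 0.0,
            "stop": [1, 2, 3, 4, 5, 6, 7, 8.0],
            "event_interval": [1, 1, 1, 1, 0, 0, 0, 0],
            "x": [5.0, 5, 5, 5, -5, -5, -5, -5],
        })
        fit = fit_tv_cox(df, ["x"])
        assert not fit.converged
        assert fit.message


class TestMultiplicity:
    def test_bh_flat_example(self):
        q = adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_bh_stepup_example(self):
        q = adjust_bh([0.005, 0.03, 0.8])
        assert np.allclose(q, [0.015, 0.045, 0.8])

    def test_bonferroni_caps_at_one(self):
        assert np.allclose(adjust_bonferroni([0.01, 0.6]), [0.02, 1.0])


class TestScreen:
    def test_confounder_detected_noise_not(self, startstop_df):
        rng = np.random.default_rng(9)
        df = startstop_df.copy()
        # predictor tied to the event indicator -> strong signal
        df["signal"] = df["event_interval"] * 1.5 + rng.normal(scale=0.4, size=len(df))
        df["noise"] = rng.normal(size=len(df))
        res = screen_univariate(df, ["signal", "noise"], ["x2"])
        tab = res.table.set_index("predictor")
        assert tab.loc["signal", "q"] < 0.05 < tab.loc["noise", "p"]
        assert res.n_converged == 2

    def test_single_predictor_q_equals_p(self, startstop_df):
        res = screen_univariate(startstop_df, ["x1"], ["x2"])
        row = res.table.iloc[0]
        assert row["q"] == pytest.approx(row["p"])
        assert row["p_bonf"] == pytest.approx(row["p"])

    def test_prescreen_requires_both_p_and_coverage(self):
        table = pd.DataFrame({
            "predictor": ["a", "b", "c"],
            "p": [0.04, 0.04, 0.5],
        })
        res = ScreenResult(table=table, n_attempted=3, n_converged=3, failures=[])
        kept = prescreen(res, {"a": 0.6, "b": 0.4, "c": 0.9}, p_enter=0.05, min_coverage=0.5)
        assert kept == ["a"]


class TestMultivariable:
    def test_constant_availability_indicator_dropped_not_nan(self, startstop_df):
        df = startstop_df.assign(x1_obs=1.0)
        spec = MultivarSpec(forced_cols=["x2"], strata_col=None,
                            selected=["x1"], availability_cols=["x1_obs"])
        res = fit_multivariable(df, spec)
        assert "x1_obs" in res.failures
        assert np.isfinite(res.table["beta"]).all()

    def test_empty_selection_runs_forced_only(self, startstop_df):
        spec = MultivarSpec(forced_cols=["x1", "x2"], strata_col=None, selected=[])
        res = fit_multivariable(startstop_df, spec)
        assert len(res.table) == 0
        assert len(res.full_table) == 2
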