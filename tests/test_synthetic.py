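"""Synthetic cohort generator: determinism, exposure/event mechanisms, calibration."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from initsurv import ExposureCoefs, SimConfig, generate_cohort, simulate_events, simulate_exposure_history
from initsurv.synthetic import ConfigError, _simulate_structural


class TestConfigValidation:
    @pytest.mark.parametrize("field,value,fragment", [
        ("n_participants", 0, "n_participants"),
        ("visit_months", (6, 12), "visit_months"),
        ("visit_months", (0, 12, 12), "visit_months"),
        ("miss_rate_cell", 1.5, "miss_rate_cell"),
        ("n_sites", 0, "n_sites"),
    ])
    def test_invalid_config_names_field(self, field, value, fragment):
        cfg = dataclasses.replace(SimConfig(), **{field: value})
        with pytest.raises(ConfigError, match=fragment):
            cfg.validate()


class TestGenerateCohort:
    def test_fixed_seed_bit_identical(self, small_cohort):
        from initsurv import generate_cohort

        lt2, bl2, truth2 = generate_cohort(SimConfig(n_participants=250, seed=3, mc_truth_n=2000))
        lt, bl, truth = small_cohort
        pd.testing.assert_frame_equal(lt, lt2)
        pd.testing.assert_frame_equal(bl, bl2)
        assert truth == truth2

    def test_zero_missingness_gives_complete_tables(self):
        cfg = SimConfig(n_participants=60, miss_rate_visit=0.0, miss_rate_cell=0.0,
                        seed=5, mc_truth_n=1000)
        lt, _, _ = generate_cohort(cfg)
        n_visits = len(cfg.visit_months)
        assert lt.groupby("id").size().eq(n_visits).all()
        # all measurement cells observed except structurally undefined last-visit ones
        mid = lt[lt["visit"] != "fu4"]
        assert mid[["conf_l", "aux1", "alcohol_like_item"]].notna().all().all()

    def test_null_effects_give_unit_marginal_or(self):
        cfg = SimConfig(n_participants=50, psi_true=0.0, kappa_feedback=0.0,
                        delta_L=0.0, seed=7, mc_truth_n=150_000)
        _, _, truth = generate_cohort(cfg)
        assert truth.marginal_or_mc == pytest.approx(1.0, abs=0.05)

    def test_baseline_age_distribution(self):
        _, bl, _ = generate_cohort(SimConfig(n_participants=4000, seed=11, mc_truth_n=1000))
        assert bl["baseline_age_months"].mean() == pytest.approx(118.9, abs=0.5)
        assert bl["baseline_age_months"].std() == pytest.approx(7.4, abs=0.5)

    def test_no_confounding_when_feedback_and_delta_off(self):
        """Crude and confounder-adjusted exposure-event associations agree."""
        import statsmodels.api as sm

        cfg = SimConfig(n_participants=4000, kappa_feedback=0.0, delta_L=0.0,
                        a_coefs=ExposureCoefs(-0.4, 0.8, 0.3, (0.0, 0.0)),
                        eta_Z=(0.0, 0.0), seed=13, mc_truth_n=1000,
                        miss_rate_visit=0.0, miss_rate_cell=0.0, extra_outcomes={})
        sim = _simulate_structural(cfg, cfg.n_participants, np.random.default_rng(13))
        T, ev = sim["outcomes"]["alcohol_like"]
        vm = sim["visit_months"]
        rows = []
        for k in range(len(vm) - 1):
            ids = np.flatnonzero(T >= vm[k + 1])
            rows.append(np.column_stack([
                ((T[ids] == vm[k + 1]) & (ev[ids] == 1)).astype(float),
                sim["A"][ids, k], sim["L"][ids, k],
            ]))
        y, a, l = np.vstack(rows).T
        crude = sm.GLM(y, sm.add_constant(a), family=sm.families.Binomial()).fit()
        adj = sm.GLM(y, sm.add_constant(np.column_stack([a, l])),
                     family=sm.families.Binomial()).fit()
        assert crude.params[1] == pytest.approx(adj.params[1], abs=2 * adj.bse[1])


class TestExposureModel:
    def test_null_coefficients_give_half_rate(self):
        rng = np.random.default_rng(0)
        L = np.zeros((2500, 4))
        Z = np.zeros((2500, 2))
        A = simulate_exposure_history(L, Z, ExposureCoefs(0, 0, 0, (0, 0)), rng)
        assert A.mean() == pytest.approx(0.5, abs=0.02)

    def test_saturating_confounder_effect(self):
        rng = np.random.default_rng(1)
        L = np.ones((500, 3))
        Z = np.zeros((500, 2))
        A = simulate_exposure_history(L, Z, ExposureCoefs(0, 1e3, 0, (0, 0)), rng)
        assert A.mean() == 1.0

    def test_prior_exposure_persistence_matches_expit(self):
        rng = np.random.default_rng(2)
        L = np.zeros((10_000, 2))
        Z = np.zeros((10_000, 2))
        A = simulate_exposure_history(L, Z, ExposureCoefs(0, 0, 2.0, (0, 0)), rng)
        p_cond = A[A[:, 0] == 1, 1].mean()
        assert p_cond == pytest.approx(expit(2.0), abs=0.02)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            simulate_exposure_history(np.zeros((5, 3)), np.zeros((4, 2)),
                                      ExposureCoefs(), np.random.default_rng(0))


class TestEventModel:
    def test_impossible_hazard_censors_everyone(self):
        rng = np.random.default_rng(0)
        A = L = np.zeros((200, 4))
        Z = np.zeros((200, 2))
        T, ev = simulate_events(A, L, Z, 0.7, 0.5, (0.1, 0.1), (-np.inf, 0.0),
                                [6, 12, 18, 24], rng)
        assert ev.sum() == 0 and (T == 24).all()

    def test_per_interval_odds_ratio_matches_psi(self):
        """With psi=log 2 and flat p0=0.02, exposed:unexposed interval odds ~ 2."""
        rng = np.random.default_rng(3)
        n = 30_000
        A = (np.arange(n) % 2).reshape(-1, 1) * np.ones((1, 4))
        L = np.zeros((n, 4))
        Z = np.zeros((n, 2))
        T, ev = simulate_events(A, L, Z, np.log(2), 0.0, (0.0, 0.0),
                                (logit(0.02), 0.0), [6, 12, 18, 24], rng)
        times = np.array([6, 12, 18, 24])
        odds = {}
        for a in (0, 1):
            sel = A[:, 0] == a
            n_iv = np.searchsorted(times, T[sel], side="right").sum()
            d = ev[sel].sum()
            odds[a] = d / (n_iv - d)
        assert odds[1] / odds[0] == pytest.approx(2.0, rel=0.1)

    def test_default_calibration_hits_cohort_incidences(self):
        cfg = SimConfig(n_participants=60_000, seed=17, mc_truth_n=1000)
        sim = _simulate_structural(cfg, cfg.n_participants, np.random.default_rng(17))
        _, ev_alc = sim["outcomes"]["alcohol_like"]
        _, ev_nic = sim["outcomes"]["nicotine_like"]
        assert ev_alc.mean() == pytest.approx(0.365, abs=0.01)
        assert ev_nic.mean() == pytest.approx(0.0544, abs=0.005)
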