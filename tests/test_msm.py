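"""Stabilized IPTW machinery and weighted pooled logistic MSM."""

import numpy as np
import pandas as pd
import pytest

from initsurv import (
    compute_stabilized_weights,
    dichotomize,
    fdr_across_exposures,
    fit_pooled_logistic,
    fit_treatment_models,
    rcs_basis,
    run_msm,
    weight_diagnostics,
)
from initsurv.experiments import feedback_intervals, reference_config
from initsurv.msm import MSMResult, MsmError, WeightSet


class TestDichotomize:
    def test_median_split(self):
        assert dichotomize([1, 2, 3, 4]).tolist() == [0, 0, 1, 1]

    def test_ties_at_median_go_low(self):
        assert dichotomize([5, 5, 5, 9]).tolist() == [0, 0, 0, 1]

    def test_binary_passthrough(self):
        assert dichotomize([0, 1, 1, 0], declared_binary=True).tolist() == [0, 1, 1, 0]

    def test_all_missing_rejected(self):
        with pytest.raises(MsmError):
            dichotomize([np.nan, np.nan])


class TestStabilizedWeights:
    def test_identical_models_give_unit_weights(self):
        p = np.array([0.3, 0.6, 0.2])
        ws = compute_stabilized_weights(p, p, np.array([1, 0, 1]), np.array([1, 1, 1]))
        assert np.allclose(ws.weights, 1.0)

    def test_two_interval_hand_product(self):
        """SW_1 = 0.5/0.8; SW_2 = SW_1 * (0.5/0.6); reproduced to 1e-12."""
        ws = compute_stabilized_weights(
            num_probs=[0.5, 0.5], den_probs=[0.8, 0.4], A=[1, 0], ids=[7, 7],
            clip=0.001, trunc_q=1.0,
        )
        assert ws.weights[0] == pytest.approx(0.625, abs=1e-12)
        assert ws.weights[1] == pytest.approx(0.625 * (0.5 / 0.6), abs=1e-12)

    def test_cumulative_product_restarts_per_participant(self):
        ws = compute_stabilized_weights([0.5, 0.5], [0.8, 0.8], [1, 1], ids=[1, 2],
                                        trunc_q=1.0)
        assert np.allclose(ws.weights, 0.625)

    def test_truncation_caps_extreme_weight(self):
        n = 200
        num = np.full(n, 0.5)
        den = np.full(n, 0.5)
        den[0] = 0.001  # one extreme inverse-probability blow-up
        A = np.ones(n)
        ws = compute_stabilized_weights(num, den, A, np.arange(n), clip=0.0005, trunc_q=0.99)
        assert ws.max <= np.quantile(np.where(np.arange(n) == 0, 500.0, 1.0), 0.99) + 1e-9
        assert ws.max < 500.0  # post-truncation max below the raw blow-up

    def test_mean_near_one_under_correct_specification(self):
        iv = feedback_intervals(reference_config(n=2000), seed=21)
        knots = np.unique(np.percentile(iv["stop"], (5, 35, 65, 95)))
        num, den, *_ = fit_treatment_models(
            iv, "expo_a", ["sex", "age_z"], ["conf_l"],
            time_basis=lambda t: rcs_basis(t, knots=knots),
        )
        ws = compute_stabilized_weights(num, den, iv["expo_a"], iv["id"])
        assert 0.9 <= ws.mean <= 1.1


class TestTreatmentModels:
    def test_logistic_coefficients_recovered(self):
        """Simulated treatment model with known coefficients, ~5000 intervals."""
        iv = feedback_intervals(reference_config(n=1000), seed=33)
        _, _, num_res, den_res = fit_treatment_models(
            iv, "expo_a", ["sex", "age_z"], ["conf_l"],
            time_basis=lambda t: t[:, None],
        )
        # denominator design: [const, prev, sex, age_z, t, conf_l]
        truth = {"const": -0.4, "prev": 0.3, "sex": 0.2, "age_z": 0.1, "conf_l": 0.6}
        est = dict(zip(["const", "prev", "sex", "age_z", "t", "conf_l"], den_res.params))
        ses = dict(zip(["const", "prev", "sex", "age_z", "t", "conf_l"], den_res.bse))
        for k, v in truth.items():
            assert est[k] == pytest.approx(v, abs=2.5 * ses[k])

    def test_no_confounding_means_unit_weights(self):
        """If L does not enter treatment assignment, SW ~ 1 within noise."""
        cfg = reference_config(n=1500)
        cfg.a_coefs.confounder = 0.0
        iv = feedback_intervals(cfg, seed=5)
        num, den, *_ = fit_treatment_models(iv, "expo_a", ["sex", "age_z"], ["conf_l"])
        ws = compute_stabilized_weights(num, den, iv["expo_a"], iv["id"])
        assert abs(ws.mean - 1.0) < 0.02
        assert np.percentile(np.abs(ws.weights - 1.0), 95) < 0.25

    def test_missing_treatment_rejected(self):
        iv = feedback_intervals(reference_config(n=50), seed=1)
        iv.loc[0, "expo_a"] = np.nan
        with pytest.raises(MsmError, match="missing"):
            fit_treatment_models(iv, "expo_a", [], [])


class TestDiagnostics:
    def _ws(self, w):
        w = np.asarray(w, float)
        return WeightSet.from_weights(w, 0.99, 0.01, w.max())

    def test_unit_weights_pass(self):
        ok, rep = weight_diagnostics(self._ws(np.ones(100)), prevalence=0.4)
        assert ok and rep["reasons"] == []

    def test_low_prevalence_fails(self):
        ok, rep = weight_diagnostics(self._ws(np.ones(100)), prevalence=0.01)
        assert not ok and "prevalence" in rep["reasons"][0]

    def test_extreme_mean_weight_fails(self):
        ok, rep = weight_diagnostics(self._ws(np.full(100, 1.3)), prevalence=0.4)
        assert not ok and "mean weight" in rep["reasons"][0]

    def test_low_ess_fails(self):
        # mean stays ~1 but one dominant weight collapses the effective n
        w = np.full(100, 0.5)
        w[0] = 50.0
        ok, rep = weight_diagnostics(self._ws(w), prevalence=0.4)
        assert not ok
        assert any("ESS" in r for r in rep["reasons"])


class TestPooledLogistic:
    def test_unit_weights_match_unweighted_fit(self):
        iv = feedback_intervals(reference_config(n=800), seed=2)
        psi_w, *_ = fit_pooled_logistic(iv, "expo_a", ["sex"], weights=np.ones(len(iv)))
        psi_u, *_ = fit_pooled_logistic(iv, "expo_a", ["sex"], weights=None)
        assert psi_w == pytest.approx(psi_u, abs=1e-8)

    def test_rcs_basis_linear_fallback_and_shape(self):
        t = np.arange(100, dtype=float)
        assert rcs_basis(t, knots=[1.0, 2.0]).shape == (100, 1)
        knots = np.percentile(t, (5, 35, 65, 95))
        b = rcs_basis(np.concatenate([t, t[-1] + np.arange(1, 6)]), knots=knots)
        assert b.shape == (105, 3)  # 4 knots -> linear + 2 restricted cubic terms
        # natural spline: linear beyond the boundary knots
        tail = b[-5:, :]
        assert np.allclose(np.diff(tail, n=2, axis=0), 0.0, atol=1e-8)


class TestFdrFamily:
    def test_single_retained_q_equals_p(self):
        res = [MSMResult(exposure="a", p=0.03, retained=True)]
        assert fdr_across_exposures(res)[0].q == pytest.approx(0.03)

    def test_non_retained_excluded_from_family(self):
        res = [
            MSMResult(exposure="a", p=0.04, retained=True),
            MSMResult(exposure="b", p=0.01, retained=False),
        ]
        out = fdr_across_exposures(res)
        assert out[0].q == pytest.approx(0.04)  # m=1, not min(2*0.01, ...)
        assert np.isnan(out[1].q)

    def test_all_unit_pvalues(self):
        res = [MSMResult(exposure=e, p=1.0, retained=True) for e in "ab"]
        assert [r.q for r in fdr_across_exposures(res)] == [1.0, 1.0]


class TestRunMsm:
    def test_constant_exposure_excluded_by_prevalence(self):
        iv = feedback_intervals(reference_config(n=300), seed=4)
        iv["always"] = 1.0
        res = run_msm(iv, {"always": {"column": "always", "binary": True}}, ["sex"])
        assert not res[0].retained and "prevalence" in res[0].reason

    def test_reference_exposure_retained_with_positive_effect(self):
        iv = feedback_intervals(reference_config(n=2000), seed=6)
        res = run_msm(
            iv,
            {"expo_a": {"column": "expo_a", "binary": True, "confounders": ["conf_l"]}},
            ["sex", "age_z"],
        )[0]
        assert res.retained and res.psi > 0
        assert res.weight_report["mean_w"] == pytest.approx(1.0, abs=0.1)
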