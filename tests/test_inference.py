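"""Indirect-effect tests and hazard-scale decomposition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hdmedsurv as hm
from hdmedsurv.inference import CounterfactualParams, run_mediation_tests


class TestMediatorModel:
    def test_matches_statsmodels(self, sim_small):
        import statsmodels.api as sm
        _, data, _ = sim_small
        mf = hm.fit_mediator_model(data, 2)
        D = sm.add_constant(np.column_stack([data.exposure, data.covariates]))
        ref = sm.OLS(data.mediators[:, 2], D).fit()
        assert mf.alpha_hat == pytest.approx(ref.params[1], rel=1e-10)
        assert mf.se_alpha == pytest.approx(ref.bse[1], rel=1e-8)
        assert mf.p_alpha == pytest.approx(ref.pvalues[1], rel=1e-6)
        assert mf.residual_variance == pytest.approx(ref.mse_resid, rel=1e-10)

    def test_noiseless_data_is_interpolated_exactly(self):
        rng = np.random.default_rng(5)
        n = 40
        X = (rng.uniform(size=n) < 0.5).astype(float)
        Z = rng.uniform(size=(n, 2))
        M = (0.3 + 0.5 * X + Z @ np.array([0.3, 0.2]))[:, None]
        data = hm.SurvivalDataset(time=np.arange(1, n + 1, dtype=float),
                                  event=np.ones(n), exposure=X, covariates=Z,
                                  mediators=M)
        mf = hm.fit_mediator_model(data, 0)
        assert mf.alpha_hat == pytest.approx(0.5, abs=1e-10)
        assert mf.intercept_hat == pytest.approx(0.3, abs=1e-10)

    def test_recovery_on_simulated(self, sim_mid):
        cfg, data, _ = sim_mid
        mf = hm.fit_mediator_model(data, 0)
        assert abs(mf.alpha_hat - 0.5) < 3.5 * mf.se_alpha


class TestSobel:
    def test_hand_example(self):
        se, z, p = hm.sobel_test(1.0, 0.5, 1.0, 0.5)
        assert se == pytest.approx(math.sqrt(0.5), abs=1e-4)
        assert z == pytest.approx(1.4142, abs=1e-4)
        assert p == pytest.approx(0.1573, abs=1e-4)

    def test_degenerate_null_convention(self):
        se, z, p = hm.sobel_test(0.0, 0.0, 0.0, 0.0)
        assert p == 1.0
        # alpha = 0 with positive SEs: z driven by the beta*se_alpha term
        se, z, p = hm.sobel_test(0.0, 0.3, 2.0, 0.4)
        assert se == pytest.approx(2.0 * 0.3)
        assert p == 1.0  # product is exactly 0

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            hm.sobel_test(1.0, -0.1, 1.0, 0.5)

    @given(st.floats(0.01, 5.0), st.floats(0.01, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_p_monotone_decreasing_in_product(self, a1, a2):
        # p-value strictly ordered by |alpha*beta| at fixed SEs
        lo, hi = sorted([a1, a2])
        if lo == hi:
            return
        _, _, p_lo = hm.sobel_test(lo, 0.2, 1.0, 0.2)
        _, _, p_hi = hm.sobel_test(hi, 0.2, 1.0, 0.2)
        assert p_hi <= p_lo


class TestJointAndBonferroni:
    @pytest.mark.parametrize("pa, pb, expect", [(0.2, 0.01, 0.2),
                                                (0.03, 0.03, 0.03),
                                                (0.0, 1.0, 1.0)])
    def test_joint_is_max(self, pa, pb, expect):
        assert hm.joint_test(pa, pb) == expect

    def test_joint_rejects_bad_p(self):
        with pytest.raises(ValueError):
            hm.joint_test(-0.1, 0.5)

    @pytest.mark.parametrize("p, m, expect", [(0.01, 6, 0.06), (0.5, 3, 1.0),
                                              (0.2, 1, 0.2)])
    def test_bonferroni(self, p, m, expect):
        assert hm.bonferroni_adjust(p, m) == pytest.approx(expect)

    def test_adjustment_preserves_order(self):
        raw = np.array([0.001, 0.01, 0.04, 0.2, 0.9])
        adj = [hm.bonferroni_adjust(p, 5) for p in raw]
        assert all(a <= b for a, b in zip(adj, adj[1:]))
        assert all(a >= r for a, r in zip(adj, raw))


class TestDecomposition:
    def test_worked_hazard_ratio_arithmetic(self):
        # log-scale indirect effects exponentiate to the hazard ratios
        assert math.exp(0.2229) == pytest.approx(1.2497, abs=5e-5)
        assert math.exp(0.1388) == pytest.approx(1.1489, abs=5e-5)

    def _decomp(self, data, cfg):
        support = np.flatnonzero(cfg.beta)
        refit = hm.refit_unpenalized(data, support)
        fits = [hm.fit_mediator_model(data, int(k)) for k in support]
        return hm.decompose_effects(refit.coefficients[0],
                                    refit.standard_errors[0], fits, refit)

    def test_identity_total_is_direct_plus_indirect(self, sim_small):
        cfg, data, _ = sim_small
        dec = self._decomp(data, cfg)
        assert dec.total_log_hr == dec.direct_log_hr + dec.total_indirect_log_hr
        tab = dec.hr_table()
        np.testing.assert_allclose(tab["hr"], np.exp(tab["log_hr"]), rtol=1e-15)

    def test_null_contrast_gives_unit_hazard_ratios(self, sim_small):
        cfg, data, _ = sim_small
        support = np.flatnonzero(cfg.beta)
        refit = hm.refit_unpenalized(data, support)
        fits = [hm.fit_mediator_model(data, int(k)) for k in support]
        dec = hm.decompose_effects(refit.coefficients[0],
                                   refit.standard_errors[0], fits, refit,
                                   x_from=1.0, x_to=1.0)
        assert dec.total_log_hr == 0.0
        assert all(v == 0.0 for v in dec.indirect_log_hr.values())
        assert np.all(dec.hr_table()["hr"] == 1.0)

    def test_sigma2_w_beta_accumulates(self, sim_small):
        cfg, data, _ = sim_small
        dec = self._decomp(data, cfg)
        assert dec.sigma2_W_beta > 0


class TestCounterfactual:
    def _params(self, rng):
        p = 4
        return CounterfactualParams(
            gamma=rng.normal(), theta=rng.normal(size=2),
            beta=rng.normal(size=p), alpha=rng.normal(size=p),
            c=rng.uniform(size=p), vartheta=rng.normal(size=2),
            sigma2_M=rng.uniform(0.5, 1.5, size=p), log_baseline=-0.7)

    def test_direct_contrast_cancels_everything_but_gamma(self):
        rng = np.random.default_rng(11)
        pr = self._params(rng)
        z = rng.normal(size=2)
        diff = (hm.counterfactual_log_hazard(pr, 1.0, 0.0, z)
                - hm.counterfactual_log_hazard(pr, 0.0, 0.0, z))
        assert diff == pytest.approx(pr.gamma, abs=1e-12)

    def test_indirect_contrast_gives_sum_of_products(self):
        rng = np.random.default_rng(12)
        pr = self._params(rng)
        z = rng.normal(size=2)
        diff = (hm.counterfactual_log_hazard(pr, 1.0, 1.0, z)
                - hm.counterfactual_log_hazard(pr, 1.0, 0.0, z))
        assert diff == pytest.approx(float(np.sum(pr.alpha * pr.beta)), abs=1e-12)

    def test_all_zero_coefficients_leave_baseline_plus_variance(self):
        pr = CounterfactualParams(
            gamma=0.0, theta=np.zeros(2), beta=np.zeros(3), alpha=np.zeros(3),
            c=np.ones(3), vartheta=np.zeros(2), sigma2_M=np.ones(3),
            log_baseline=-1.5)
        val = hm.counterfactual_log_hazard(pr, 1.0, 1.0, np.ones(2))
        assert val == pytest.approx(-1.5)  # beta = 0 kills the variance term


class TestMediationTable:
    def test_adjustment_factor_is_s2_size(self, sim_mid):
        cfg, data, _ = sim_mid
        support = np.flatnonzero(cfg.beta)
        refit = hm.refit_unpenalized(data, support)
        fits = [hm.fit_mediator_model(data, int(k)) for k in support]
        res = run_mediation_tests(data, refit, fits)
        m = len(support)
        np.testing.assert_allclose(
            res.table["p_sobel_adj"],
            np.minimum(res.table["p_sobel_raw"] * m, 1.0))
        assert set(res.significant("sobel")).issubset(set(support.tolist()))
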