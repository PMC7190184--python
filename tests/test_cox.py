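"""Cox partial-likelihood machinery against hand enumeration, brute force,
and the lifelines reference implementation."""

import numpy as np
import pytest

import hdmedsurv as hm
from hdmedsurv import _kernels
from hdmedsurv.cox import sort_structure
from hdmedsurv.exceptions import (ConvergenceWarning, NoEventsError,
                                  SingularInformationError)


def brute_lpl(time, event, X, beta):
    """Independent Breslow log-partial-likelihood oracle by risk-set enumeration."""
    eta = X @ beta
    out = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = time >= time[i]
            out += eta[i] - np.log(np.sum(np.exp(eta[risk])))
    return out


class TestLogPartialLikelihood:
    def test_two_subject_hand_example(self):
        # times (1,2), both events, single column (0,1), coef 0:
        # risk sets {1,2} then {2} -> -log 2 - log 1
        P = np.array([[0.0], [1.0]])
        delta = np.array([1.0, 1.0])
        order, first, last = sort_structure(np.array([1.0, 2.0]))
        lpl = _kernels.cox_lpl(P, delta, first, np.array([0.0]))
        assert lpl == pytest.approx(-np.log(2.0), abs=1e-12)

    def test_zero_coefs_is_minus_sum_log_risk_sizes(self, toy_data):
        lpl = hm.log_partial_likelihood(toy_data, np.zeros(2 + 3),
                                        mediator_cols=(0, 1, 2))
        expected = -sum(np.log((toy_data.time >= toy_data.time[i]).sum())
                        for i in np.flatnonzero(toy_data.event))
        assert lpl == pytest.approx(expected, abs=1e-10)

    def test_matches_brute_force_on_grid(self, toy_data):
        X = toy_data.mediators[:, [0]]
        for b in np.linspace(-2, 2, 21):
            got = hm.log_partial_likelihood(
                toy_data, [b], mediator_cols=(0,),
                include_exposure=False, include_covariates=False)
            want = brute_lpl(toy_data.time, toy_data.event, X, np.array([b]))
            assert got == pytest.approx(want, abs=1e-10)

    def test_no_events_raises(self, toy_data):
        bad = hm.SurvivalDataset(
            time=toy_data.time, event=np.zeros(toy_data.n),
            exposure=toy_data.exposure, covariates=toy_data.covariates,
            mediators=toy_data.mediators)
        with pytest.raises(NoEventsError, match="no events"):
            hm.log_partial_likelihood(bad, np.zeros(2))

    def test_nonfinite_linear_predictor_raises(self, toy_data):
        with pytest.raises(ValueError, match="non-finite"):
            hm.log_partial_likelihood(toy_data, [np.inf, 0.0])


class TestFitCox:
    def test_agrees_with_lifelines(self, sim_small):
        _, data, _ = sim_small
        fit = hm.fit_cox(data, mediator_cols=(0, 1))
        ref = hm.fit_cox(data, mediator_cols=(0, 1), ties="efron")
        # continuous times: Breslow and Efron coincide, so lifelines is an
        # independent oracle for coefficients, SEs and the likelihood value
        np.testing.assert_allclose(fit.coefficients, ref.coefficients,
                                   rtol=1e-5, atol=1e-6)
        np.testing.assert_allclose(fit.standard_errors, ref.standard_errors,
                                   rtol=1e-4, atol=1e-6)
        assert fit.log_partial_likelihood == pytest.approx(
            ref.log_partial_likelihood, rel=1e-8)

    def test_score_zero_and_improves_on_null(self, sim_small):
        _, data, _ = sim_small
        fit = hm.fit_cox(data, mediator_cols=(0, 3, 7))
        P, names = data.design((0, 3, 7))
        order, first, last = sort_structure(data.time)
        _, grad, _ = _kernels.cox_derivs(
            np.ascontiguousarray(P[order]), data.event[order], first,
            fit.coefficients)
        assert np.max(np.abs(grad)) < 1e-5
        lpl0 = hm.log_partial_likelihood(data, np.zeros(len(names)),
                                         mediator_cols=(0, 3, 7))
        assert fit.log_partial_likelihood >= lpl0

    def test_matches_golden_section_1d(self, toy_data):
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(
            lambda b: -hm.log_partial_likelihood(
                toy_data, [b], mediator_cols=(1,), include_exposure=False,
                include_covariates=False),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10})
        fit = hm.fit_cox(toy_data, mediator_cols=(1,), include_exposure=False,
                         include_covariates=False)
        assert fit.coefficients[0] == pytest.approx(res.x, abs=1e-6)

    def test_duplicated_column_singular(self, sim_small):
        _, data, _ = sim_small
        dup = hm.SurvivalDataset(
            time=data.time, event=data.event, exposure=data.exposure,
            covariates=data.covariates,
            mediators=np.column_stack([data.mediators[:, 0], data.mediators[:, 0]]))
        with pytest.raises(SingularInformationError, match="singular information"):
            hm.fit_cox(dup, mediator_cols=(0, 1))

    def test_rank_invariance_under_time_shift_and_scale(self, sim_small):
        _, data, _ = sim_small
        fit = hm.fit_cox(data, mediator_cols=(2,))
        for transform in (lambda t: t + 7.5, lambda t: t * 3.25):
            other = hm.SurvivalDataset(
                time=transform(data.time), event=data.event,
                exposure=data.exposure, covariates=data.covariates,
                mediators=data.mediators)
            fit2 = hm.fit_cox(other, mediator_cols=(2,))
            np.testing.assert_allclose(fit2.coefficients, fit.coefficients,
                                       rtol=1e-8, atol=1e-10)

    def test_null_coverage_monte_carlo(self):
        # 1-predictor null model: estimate within 3 SE of 0 in >= 95% of seeds
        rng = np.random.default_rng(2024)
        hits = 0
        n_seeds = 200
        for _ in range(n_seeds):
            n = 30
            time = rng.exponential(size=n)
            x = rng.normal(size=(n, 1))
            order, first, last = sort_structure(time)
            beta, cov, _, _, status = _kernels.newton_cox(
                np.ascontiguousarray(x[order]), np.ones(n), first,
                np.zeros(1), 1e-9, 100)
            se = np.sqrt(cov[0, 0])
            if status == 0 and abs(beta[0]) < 3 * se:
                hits += 1
        assert hits / n_seeds >= 0.95

    def test_parameter_recovery_on_simulated_data(self, sim_mid):
        # the correctly specified outcome model includes every mediator with
        # a nonzero hazard coefficient (omitting one attenuates the rest via
        # the Cox model's non-collapsibility)
        cfg, data, _ = sim_mid
        support = tuple(np.flatnonzero(cfg.beta))
        fit = hm.fit_cox(data, mediator_cols=support)
        true_coefs = np.array([cfg.gamma, *cfg.theta,
                               *(cfg.beta[k] for k in support)])
        # 4 SE covers simultaneous comparison of 7 coefficients
        np.testing.assert_array_less(
            np.abs(fit.coefficients - true_coefs), 4.0 * fit.standard_errors)

    def test_monotone_likelihood_warns(self):
        # perfectly separating predictor: the event subjects all have larger
        # values, so the coefficient diverges
        n = 20
        time = np.concatenate([np.arange(1, 11), np.arange(11, 21)]).astype(float)
        event = np.concatenate([np.ones(10), np.zeros(10)])
        med = np.concatenate([np.zeros(10), np.ones(10)])[:, None]
        data = hm.SurvivalDataset(time=time, event=event,
                                  exposure=np.tile([0.0, 1.0], 10),
                                  covariates=np.empty((n, 0)), mediators=med)
        with pytest.warns(ConvergenceWarning):
            fit = hm.fit_cox(data, mediator_cols=(0,), include_exposure=False)
        assert not fit.converged


class TestBaselineCumulativeHazard:
    def test_single_event_null_jump(self):
        n = 10
        time = np.arange(1, n + 1, dtype=float)
        event = np.zeros(n)
        event[4] = 1.0  # risk set size 6 at t=5
        data = hm.SurvivalDataset(time=time, event=event,
                                  exposure=np.tile([0.0, 1.0], 5),
                                  covariates=np.empty((n, 0)),
                                  mediators=np.zeros((n, 1)))
        # all coefficients zero: the Breslow jump is 1 / (risk-set size)
        fit0 = hm.CoxFit(coefficients=np.zeros(1), standard_errors=np.ones(1),
                         covariance=np.eye(1), log_partial_likelihood=0.0,
                         converged=True, n_iterations=1,
                         column_names=["exposure"])
        H0 = hm.baseline_cumulative_hazard(fit0, data, include_covariates=False)
        assert H0.times.tolist() == [5.0]
        assert H0.cumhaz[0] == pytest.approx(1.0 / 6.0)
        assert H0(4.9) == 0.0 and H0(5.0) == pytest.approx(1.0 / 6.0)

    def test_matches_hand_computed_breslow(self, toy_data):
        fit = hm.fit_cox(toy_data, mediator_cols=(0,))
        H = hm.baseline_cumulative_hazard(fit, toy_data)
        P, _ = toy_data.design((0,))
        eta = P @ fit.coefficients
        expected = 0.0
        for i in np.argsort(toy_data.time):
            if toy_data.event[i]:
                risk = toy_data.time >= toy_data.time[i]
                expected += 1.0 / np.exp(eta[risk]).sum()
                assert H(toy_data.time[i]) == pytest.approx(expected, rel=1e-10)

    def test_no_events_zero_function(self, toy_data):
        data = hm.SurvivalDataset(
            time=toy_data.time, event=np.zeros(toy_data.n),
            exposure=toy_data.exposure, covariates=toy_data.covariates,
            mediators=toy_data.mediators)
        fit = hm.CoxFit(coefficients=np.zeros(2), standard_errors=np.ones(2),
                        covariance=np.eye(2), log_partial_likelihood=0.0,
                        converged=True, n_iterations=0,
                        column_names=["exposure", "Z1"])
        H = hm.baseline_cumulative_hazard(fit, data)
        assert H(np.array([0.5, 3.0, 100.0])).tolist() == [0.0, 0.0, 0.0]
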