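"""Cox proportional-hazards machinery: partial likelihood, Newton fitting,
standard errors, and the Breslow baseline cumulative hazard.

The outcome model is

    lambda_i(t | X_i, Z_i, M_i) = lambda_0(t) exp(gamma X_i + theta' Z_i
                                                  + sum_k beta_k M_{ki}),

estimated by maximizing the Breslow log partial likelihood

    l_n(Q) = sum_i delta_i { P_i' Q - log sum_{l in R_i} exp(P_l' Q) },

with risk sets R_i = {l : T_l >= T_i}. Ties are handled by the Breslow
approximation by default; the Efron correction is available via
``fit_cox(..., ties="efron")`` (delegated to lifelines).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .datasets import SurvivalDataset
from .exceptions import ConvergenceWarning, NoEventsError, SingularInformationError

NEWTON_TOL = 1e-9
NEWTON_MAXIT = 100


@dataclass
class CoxFit:
    """A fitted Cox model over an explicit design-column selection."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    covariance: np.ndarray
    log_partial_likelihood: float
    converged: bool
    n_iterations: int
    column_names: list[str] = field(default_factory=list)
    mediator_cols: tuple[int, ...] = ()
    n_fixed: int = 0  # leading unpenalized columns (exposure + covariates)

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.column_names.index(name)])

    def se(self, name: str) -> float:
        return float(self.standard_errors[self.column_names.index(name)])


def sort_structure(time: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stable ascending-time order plus tie-block boundaries.

    Returns (order, first, last) where ``first[i]``/``last[i]`` index the
    first/last sorted subject sharing ``time_sorted[i]``.
    """
    order = np.argsort(time, kind="stable")
    ts = time[order]
    n = ts.shape[0]
    first = np.empty(n, dtype=np.int64)
    last = np.empty(n, dtype=np.int64)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        first[i:j + 1] = i
        last[i:j + 1] = j
        i = j + 1
    return order, first, last


def _sorted_design(data: SurvivalDataset, mediator_cols: Sequence[int],
                   include_exposure: bool, include_covariates: bool):
    P, names = data.design(mediator_cols, include_exposure, include_covariates)
    order, first, last = sort_structure(data.time)
    return np.ascontiguousarray(P[order]), data.event[order], first, last, names


def log_partial_likelihood(data: SurvivalDataset, coefs: np.ndarray,
                           mediator_cols: Sequence[int] = (), *,
                           include_exposure: bool = True,
                           include_covariates: bool = True) -> float:
    """Breslow log partial likelihood at ``coefs`` for the selected columns."""
    if data.n_events == 0:
        raise NoEventsError("no events")
    P, delta, first, last, names = _sorted_design(
        data, mediator_cols, include_exposure, include_covariates)
    coefs = np.asarray(coefs, dtype=np.float64)
    if coefs.shape != (P.shape[1],):
        raise ValueError(f"expected {P.shape[1]} coefficients, got {coefs.shape}")
    eta = P @ coefs
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    return float(_kernels.cox_lpl(P, delta, first, coefs))


def fit_cox(data: SurvivalDataset, mediator_cols: Sequence[int] = (), *,
            include_exposure: bool = True, include_covariates: bool = True,
            ties: str = "breslow", init: np.ndarray | None = None,
            tol: float = NEWTON_TOL, max_iter: int = NEWTON_MAXIT) -> CoxFit:
    """Maximum partial-likelihood fit on columns ``[X | Z | M[:, cols]]``.

    Standard errors come from the inverse observed information at the
    optimum. Exactly collinear columns raise
    :class:`SingularInformationError`; monotone likelihood (the separation
    analogue) returns ``converged=False`` with a :class:`ConvergenceWarning`.
    """
    if data.n_events == 0:
        raise NoEventsError("no events")
    mediator_cols = tuple(mediator_cols)
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie rule {ties!r}")
    P, delta, first, last, names = _sorted_design(
        data, mediator_cols, include_exposure, include_covariates)
    c = P.shape[1]
    if c >= data.n_events:
        warnings.warn(
            f"{c} design columns with only {data.n_events} events",
            ConvergenceWarning, stacklevel=2)
    n_fixed = data.n_fixed_columns(include_exposure, include_covariates)
    if ties == "efron":
        return _fit_efron(data, P, delta, names, mediator_cols, n_fixed)
    beta0 = np.zeros(c) if init is None else np.asarray(init, dtype=np.float64).copy()
    beta, cov, lpl, n_iter, status = _kernels.newton_cox(
        P, delta, first, beta0, tol, max_iter)
    if status == 1:
        raise SingularInformationError("singular information")
    converged = status == 0
    if converged and np.max(np.abs(beta)) > 15.0:
        # likelihood went flat at an extreme coefficient: treat as the
        # monotone-likelihood (separation) case rather than a real optimum
        converged = False
    if not converged:
        warnings.warn(
            "Cox fit did not converge (possible monotone likelihood)",
            ConvergenceWarning, stacklevel=2)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return CoxFit(coefficients=beta, standard_errors=se, covariance=cov,
                  log_partial_likelihood=float(lpl), converged=converged,
                  n_iterations=int(n_iter), column_names=names,
                  mediator_cols=mediator_cols, n_fixed=n_fixed)


def _fit_efron(data: SurvivalDataset, P, delta, names, mediator_cols, n_fixed) -> CoxFit:
    # Efron tie correction: delegate to lifelines' reference implementation
    import pandas as pd
    from lifelines import CoxPHFitter

    df = pd.DataFrame(P, columns=names)
    df["__time"] = np.sort(data.time, kind="stable")
    df["__event"] = delta
    fitter = CoxPHFitter()
    fitter.fit(df, duration_col="__time", event_col="__event")
    coefs = fitter.params_.loc[names].to_numpy()
    se = fitter.standard_errors_.loc[names].to_numpy()
    cov = fitter.variance_matrix_.loc[names, names].to_numpy()
    return CoxFit(coefficients=coefs, standard_errors=se, covariance=cov,
                  log_partial_likelihood=float(fitter.log_likelihood_),
                  converged=True, n_iterations=-1, column_names=list(names),
                  mediator_cols=tuple(mediator_cols), n_fixed=n_fixed)


@dataclass
class BreslowEstimate:
    """Breslow step estimate of the baseline cumulative hazard.

    ``times`` are the distinct event times (ascending); ``cumhaz`` the
    cumulative hazard just after each. Evaluation is right-continuous.
    """

    times: np.ndarray
    cumhaz: np.ndarray

    def __call__(self, t):
        t = np.asarray(t, dtype=np.float64)
        idx = np.searchsorted(self.times, t, side="right")
        padded = np.concatenate(([0.0], self.cumhaz))
        out = padded[idx]
        return float(out) if out.ndim == 0 else out


def baseline_cumulative_hazard(fit: CoxFit, data: SurvivalDataset, *,
                               include_exposure: bool = True,
                               include_covariates: bool = True) -> BreslowEstimate:
    """Breslow estimator H0(t) = sum_{event times t_i <= t} d_i / S0(t_i)."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    P, delta, first, last, _ = _sorted_design(
        data, fit.mediator_cols, include_exposure, include_covariates)
    if delta.sum() == 0:
        return BreslowEstimate(times=np.empty(0), cumhaz=np.empty(0))
    eta = P @ fit.coefficients
    e = np.exp(eta - eta.max())
    ts = np.sort(data.time, kind="stable")
    # suffix sums of exp(eta); risk set of an event at index i starts at first[i]
    suffix = np.cumsum(e[::-1])[::-1]
    jumps: dict[float, float] = {}
    scale = np.exp(-eta.max())
    for i in np.flatnonzero(delta):
        t = ts[i]
        jumps[t] = jumps.get(t, 0.0) + scale / suffix[first[i]]
    times = np.array(sorted(jumps))
    cumhaz = np.cumsum([jumps[t] for t in times])
    return BreslowEstimate(times=times, cumhaz=cumhaz)
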