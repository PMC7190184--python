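"""Penalized Cox variable selection over the screened mediator set.

Solves

    beta_hat = argmax_beta { (1/n) l_n(beta) - sum_k P_lambda(beta_k) }

by iteratively reweighted least squares with coordinate descent, where
P_lambda is the minimax concave penalty (MCP, default) or the LASSO.
Exposure and covariates are never penalized. The MCP with shape a > 1 is

    P_lambda(b) = lambda |b| - b^2 / (2a)   for |b| <= a lambda,
                  a lambda^2 / 2            otherwise,

with derivative (a lambda - |b|)_+ / a in |b|: LASSO-like shrinkage near
zero, no shrinkage beyond a*lambda, hence nearly unbiased large effects.

lambda is chosen by BIC (default) or k-fold cross-validated partial
likelihood, and the selected set S2 = {k : beta_hat_k != 0} is refit
unpenalized to provide the coefficient estimates and standard errors used
by the downstream indirect-effect tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .cox import CoxFit, fit_cox, sort_structure
from .datasets import SurvivalDataset
from .exceptions import ConvergenceWarning

CD_MAX_REFRESH = 60


@dataclass
class PenaltyConfig:
    kind: str = "mcp"                      # "mcp" | "lasso"
    a: float = 3.0                         # MCP shape (ncvreg convention)
    lambda_grid: np.ndarray | str = "auto"
    lambda_selection: str = "ebic"         # "ebic" | "bic" | "cross_validation"
    ebic_gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float | None = None  # auto: 0.01 if n > n_penalized else 0.05
    tol: float = 1e-7
    max_iter: int = CD_MAX_REFRESH
    dfmax: int | None = None               # auto: min(|S1|, max(50, n // 20))
    n_folds: int = 10
    cv_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("mcp", "lasso"):
            raise ValueError(f"unknown penalty kind {self.kind!r}")
        if self.a <= 1.0:
            raise ValueError("MCP shape parameter a must exceed 1")
        if self.lambda_selection not in ("ebic", "bic", "cross_validation"):
            raise ValueError(f"unknown lambda selection {self.lambda_selection!r}")
        if isinstance(self.lambda_grid, str):
            if self.lambda_grid != "auto":
                raise ValueError("lambda_grid must be an array or 'auto'")
        else:
            self.lambda_grid = np.asarray(self.lambda_grid, dtype=np.float64)
            if np.any(np.diff(self.lambda_grid) >= 0):
                raise ValueError("lambda_grid must be strictly decreasing")


@dataclass
class PenalizedPath:
    """Coefficient path over the lambda grid, on the original scale.

    ``coefficients[l]`` holds (exposure, covariates, S1 mediators) at
    ``lambdas[l]``; ``mediator_coefficients`` is the penalized block only.
    """

    lambdas: np.ndarray
    coefficients: np.ndarray        # (L, n_fixed + |S1|)
    log_partial_likelihoods: np.ndarray
    converged: np.ndarray
    df: np.ndarray
    S1: np.ndarray
    n_fixed: int
    column_names: list[str] = field(default_factory=list)

    @property
    def mediator_coefficients(self) -> np.ndarray:
        return self.coefficients[:, self.n_fixed:]


@dataclass
class SelectionResult:
    S2: np.ndarray
    penalized_fit: np.ndarray       # coefficient vector at lambda_chosen
    refit: CoxFit
    lambda_chosen: float
    path: PenalizedPath


def mcp_penalty(beta, lam: float, a: float = 3.0):
    """MCP value and derivative (elementwise); derivative is signed by beta."""
    if a <= 1.0:
        raise ValueError("MCP shape parameter a must exceed 1")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    beta = np.asarray(beta, dtype=np.float64)
    ab = np.abs(beta)
    pen = np.where(ab <= a * lam, lam * ab - ab**2 / (2.0 * a), 0.5 * a * lam**2)
    deriv = np.sign(beta) * np.clip(a * lam - ab, 0.0, None) / a
    # at the origin the subgradient magnitude is lambda (matches LASSO slope)
    deriv = np.where(ab == 0.0, lam, deriv)
    if pen.ndim == 0:
        return float(pen), float(deriv)
    return pen, deriv


def _prepare(data: SurvivalDataset, S1: Sequence[int]):
    S1 = np.asarray(list(S1), dtype=np.int64)
    fixed, fixed_names = data.design((), True, True)
    med = data.mediators[:, S1]
    sd = med.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    med_std = (med - med.mean(axis=0)) / sd
    P = np.column_stack([fixed, med_std])
    order, first, last = sort_structure(data.time)
    names = fixed_names + [str(data.mediator_ids[k]) for k in S1]
    return (S1, np.ascontiguousarray(P[order]), data.event[order], first, last,
            sd, fixed.shape[1], names)


def _auto_grid(P, delta, first, last, n_fixed, config: PenaltyConfig,
               base_coefs: np.ndarray) -> np.ndarray:
    n = P.shape[0]
    beta0 = np.concatenate([base_coefs, np.zeros(P.shape[1] - n_fixed)])
    g, w, _ = _kernels._subject_gw(P @ beta0, delta, first, last)
    u = np.abs(P[:, n_fixed:].T @ g) / n
    lam_max = float(u.max()) * 1.0001 + 1e-12
    if config.lambda_min_ratio is not None:
        ratio = config.lambda_min_ratio
    else:
        ratio = 0.01 if n > (P.shape[1] - n_fixed) else 0.05
    return np.exp(np.linspace(np.log(lam_max), np.log(ratio * lam_max),
                              config.n_lambda))


def fit_penalized_cox(data: SurvivalDataset, S1: Sequence[int],
                      config: PenaltyConfig | None = None) -> PenalizedPath:
    """Warm-started MCP/LASSO path for the Cox model on (X, Z, M[S1]).

    Mediator columns are standardized internally; returned coefficients are
    on the original scale. Non-convergence at a lambda is recorded in
    ``converged`` and the path continues.
    """
    config = config or PenaltyConfig()
    S1, P, delta, first, last, sd, n_fixed, names = _prepare(data, S1)
    n = data.n
    if len(S1) >= n:
        warnings.warn(f"|S1| = {len(S1)} >= n = {n}; selection may be unstable",
                      ConvergenceWarning, stacklevel=2)
    base = fit_cox(data)
    if isinstance(config.lambda_grid, str):
        lambdas = _auto_grid(P, delta, first, last, n_fixed, config, base.coefficients)
    else:
        lambdas = config.lambda_grid
    beta0 = np.concatenate([base.coefficients, np.zeros(len(S1))])
    kind = 1 if config.kind == "lasso" else 0
    dfmax = config.dfmax if config.dfmax is not None else min(
        len(S1), max(50, n // 20))
    coefs, lpls, flags, n_valid = _kernels.cd_path(
        P, delta, first, last, n_fixed, lambdas, config.a, kind,
        config.tol, config.max_iter, beta0, dfmax)
    lambdas = lambdas[:n_valid]
    coefs = coefs[:n_valid].copy()
    lpls = lpls[:n_valid]
    flags = flags[:n_valid]
    coefs[:, n_fixed:] /= sd[None, :]
    df = n_fixed + (coefs[:, n_fixed:] != 0).sum(axis=1)
    n_bad = int((flags != 0).sum())
    if n_bad:
        warnings.warn(f"coordinate descent did not converge at {n_bad} lambda values",
                      ConvergenceWarning, stacklevel=2)
    return PenalizedPath(lambdas=lambdas, coefficients=coefs,
                         log_partial_likelihoods=lpls,
                         converged=(flags == 0), df=df, S1=S1,
                         n_fixed=n_fixed, column_names=names)


def _subset(data: SurvivalDataset, idx: np.ndarray) -> SurvivalDataset:
    return SurvivalDataset(
        time=data.time[idx], event=data.event[idx], exposure=data.exposure[idx],
        covariates=data.covariates[idx], mediators=data.mediators[idx],
        subject_ids=data.subject_ids[idx], mediator_ids=data.mediator_ids,
        covariate_names=list(data.covariate_names))


def _cv_folds(event: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    # folds stratified by event status
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed % (2**31)))
    assign = np.empty(event.shape[0], dtype=np.int64)
    for group in (np.flatnonzero(event == 1), np.flatnonzero(event == 0)):
        perm = rng.permutation(group)
        assign[perm] = np.arange(perm.size) % n_folds
    return [np.flatnonzero(assign == f) for f in range(n_folds)]


def select_lambda(path: PenalizedPath, data: SurvivalDataset,
                  config: PenaltyConfig | None = None) -> float:
    """Pick lambda by EBIC (default), plain BIC, or cross-validation.

    EBIC = -2 l_n(beta_hat_lambda)
           + [log(n_events) + 2 gamma log(|S1|)] * df_lambda

    with df = active penalized columns + unpenalized columns and gamma =
    ``ebic_gamma``. The log(|S1|) term guards against the strongest of the
    |S1| screened null mediators (whose best chi-square statistic grows
    like 2 log |S1|), which ordinary BIC (gamma = 0) cannot resist when the
    candidate set is large relative to log(n). Ties go to the larger lambda
    (sparser model). Cross-validation maximizes the held-out partial
    likelihood l_full(beta_train) - l_train(beta_train), folds stratified
    by event status.
    """
    config = config or PenaltyConfig()
    if path.lambdas.size == 0:
        raise ValueError("empty path")
    if config.lambda_selection in ("bic", "ebic"):
        gamma = config.ebic_gamma if config.lambda_selection == "ebic" else 0.0
        penalty_rate = np.log(max(data.n_events, 2)) + 2.0 * gamma * np.log(
            max(len(path.S1), 2))
        crit = -2.0 * path.log_partial_likelihoods + penalty_rate * path.df
        return float(path.lambdas[int(np.argmin(crit))])
    # cross-validated partial likelihood: cv_l = l_full(beta_train) - l_train(beta_train)
    folds = _cv_folds(data.event, config.n_folds, config.cv_seed)
    S1_full, P_full, delta_full, first_full, last_full, sd_full, n_fixed, _ = _prepare(
        data, path.S1)
    cv = np.zeros(path.lambdas.size)
    kind = 1 if config.kind == "lasso" else 0
    for fold in folds:
        train = np.setdiff1d(np.arange(data.n), fold)
        dtrain = _subset(data, train)
        S1t, Pt, dt, ft, lt, sdt, nf, _ = _prepare(dtrain, path.S1)
        base = fit_cox(dtrain)
        beta0 = np.concatenate([base.coefficients, np.zeros(len(path.S1))])
        coefs, lpls_train, _, nv = _kernels.cd_path(
            Pt, dt, ft, lt, nf, path.lambdas, config.a, kind,
            config.tol, config.max_iter, beta0, len(path.S1) + 1)
        for li in range(min(path.lambdas.size, nv)):
            b = coefs[li].copy()
            b[nf:] /= sdt
            b_std = b.copy()
            b_std[nf:] *= sd_full  # express on the full-data standardized scale
            lpl_full = _kernels.cox_lpl(P_full, delta_full, first_full, b_std)
            cv[li] += lpl_full - lpls_train[li]
    return float(path.lambdas[int(np.argmax(cv))])


def refit_unpenalized(data: SurvivalDataset, S2: Sequence[int]) -> CoxFit:
    """Unpenalized Cox refit on (X, Z, S2 mediators).

    Supplies the beta_hat_k and SE(beta_hat_k) used by the Sobel and joint
    tests, and gamma_hat for the direct effect. With S2 empty this is the
    exposure-plus-covariates model, whose gamma estimates the total exposure
    effect given Z.
    """
    S2 = tuple(int(k) for k in S2)
    if len(S2) + data.q + 1 >= data.n_events:
        warnings.warn("refit has as many columns as events; estimates unstable",
                      ConvergenceWarning, stacklevel=2)
    return fit_cox(data, mediator_cols=S2)


def select_mediators(data: SurvivalDataset, S1: Sequence[int],
                     config: PenaltyConfig | None = None) -> SelectionResult:
    """Full selection stage: path -> lambda choice -> S2 -> unpenalized refit."""
    config = config or PenaltyConfig()
    path = fit_penalized_cox(data, S1, config)
    lam = select_lambda(path, data, config)
    li = int(np.argmin(np.abs(path.lambdas - lam)))
    med_coefs = path.mediator_coefficients[li]
    S2 = path.S1[med_coefs != 0.0]
    refit = refit_unpenalized(data, S2)
    return SelectionResult(S2=np.sort(S2), penalized_fit=path.coefficients[li],
                           refit=refit, lambda_chosen=lam, path=path)
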