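"""Indirect-effect estimation, testing, and effect decomposition.

For each selected mediator k the indirect effect of the exposure on the
log hazard-ratio scale is the product alpha_k * beta_k: the exposure->
mediator coefficient from the linear model M_k = c_k + alpha_k X +
vartheta' Z + e_k times the mediator->outcome coefficient from the Cox
model. Its null is tested with

* the Sobel (product/delta-method) test, SE = sqrt(a^2 se_b^2 + b^2 se_a^2),
  P_raw = 2 (1 - Phi(|ab| / SE)); and
* the joint-significance (causal steps / MaxP) test,
  P_raw = max(P_alpha, P_beta), which provides no estimate.

Raw p-values are Bonferroni-adjusted over the selected set S2. The total
exposure effect decomposes on the log hazard-ratio scale into a natural
direct effect (x* - x) gamma and per-mediator natural indirect effects
(x* - x) alpha_k beta_k, derived from a log-normal approximation of the
marginalized counterfactual hazard whose variance inflation term is
sigma^2_{W beta} = sum_k beta_k^2 sigma^2_{M_k}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cox import CoxFit
from .datasets import SurvivalDataset
from .exceptions import DegenerateExposureError


@dataclass
class MediatorFit:
    """OLS fit of one mediator model M_k ~ 1 + X + Z."""

    mediator: int
    alpha_hat: float
    se_alpha: float
    intercept_hat: float
    vartheta_hat: np.ndarray
    residual_variance: float
    p_alpha: float


@dataclass
class MediationResult:
    """Per-mediator indirect-effect estimates and tests over S2."""

    table: pd.DataFrame            # one row per mediator in S2
    alpha_level: float = 0.05

    def significant(self, test: str = "sobel") -> np.ndarray:
        col = {"sobel": "p_sobel_adj", "joint": "p_joint_adj"}[test]
        return self.table.index[self.table[col] < self.alpha_level].to_numpy()


@dataclass
class EffectDecomposition:
    """Direct / indirect / total exposure effects on log-HR and HR scales."""

    x_from: float
    x_to: float
    direct_log_hr: float
    direct_se: float
    indirect_log_hr: Mapping[int, float]
    indirect_se: Mapping[int, float]
    total_indirect_log_hr: float
    total_log_hr: float
    total_se: float
    sigma2_W_beta: float
    mediator_labels: Mapping[int, str] = field(default_factory=dict)
    ci_level: float = 0.95

    def _ci(self, est: float, se: float) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + self.ci_level / 2.0)
        return est - z * se, est + z * se

    def hr_table(self) -> pd.DataFrame:
        """Hazard-ratio summary with log-symmetric normal CIs."""
        rows = []
        lo, hi = self._ci(self.direct_log_hr, self.direct_se)
        rows.append(("direct", self.direct_log_hr, math.exp(self.direct_log_hr),
                     math.exp(lo), math.exp(hi)))
        for k, est in self.indirect_log_hr.items():
            lo, hi = self._ci(est, self.indirect_se[k])
            label = self.mediator_labels.get(k, f"M{k + 1}")
            rows.append((f"indirect:{label}", est, math.exp(est),
                         math.exp(lo), math.exp(hi)))
        lo, hi = self._ci(self.total_log_hr, self.total_se)
        rows.append(("total", self.total_log_hr, math.exp(self.total_log_hr),
                     math.exp(lo), math.exp(hi)))
        return pd.DataFrame(rows, columns=["effect", "log_hr", "hr", "hr_ci_low",
                                           "hr_ci_high"]).set_index("effect")


def fit_mediator_model(data: SurvivalDataset, k: int) -> MediatorFit:
    """OLS of mediator k on (1, X, Z) with the usual variance estimate."""
    if np.ptp(data.exposure) == 0:
        raise DegenerateExposureError("degenerate exposure")
    n = data.n
    D = np.column_stack([np.ones(n), data.exposure, data.covariates])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("rank-deficient mediator-model design")
    y = data.mediators[:, k]
    G = np.linalg.inv(D.T @ D)
    coef = G @ (D.T @ y)
    resid = y - D @ coef
    dof = n - D.shape[1]
    sigma2 = float(resid @ resid) / dof
    se_alpha = math.sqrt(max(sigma2 * G[1, 1], 0.0))
    if se_alpha > 0:
        p_alpha = 2.0 * stats.t.sf(abs(coef[1]) / se_alpha, dof)
    else:
        p_alpha = 0.0 if coef[1] != 0 else 1.0
    return MediatorFit(mediator=int(k), alpha_hat=float(coef[1]),
                       se_alpha=se_alpha, intercept_hat=float(coef[0]),
                       vartheta_hat=coef[2:].copy(), residual_variance=sigma2,
                       p_alpha=float(p_alpha))


def sobel_test(alpha_hat: float, se_alpha: float, beta_hat: float,
               se_beta: float) -> tuple[float, float, float]:
    """Sobel product test of H0: alpha*beta = 0.

    Returns (sobel_se, z, p_raw) with sobel_se the delta-method SE
    sqrt(alpha^2 se_beta^2 + beta^2 se_alpha^2). The degenerate case of a
    zero SE with a zero product yields p_raw = 1 by convention.
    """
    if se_alpha < 0 or se_beta < 0:
        raise ValueError("standard errors must be nonnegative")
    se = math.sqrt(alpha_hat**2 * se_beta**2 + beta_hat**2 * se_alpha**2)
    prod = alpha_hat * beta_hat
    if se == 0.0:
        if prod == 0.0:
            return 0.0, 0.0, 1.0
        return 0.0, math.inf, 0.0
    z = abs(prod) / se
    return se, z, float(2.0 * stats.norm.sf(z))


def joint_test(p_alpha: float, p_beta: float) -> float:
    """Joint-significance (MaxP) p-value: max of the two path p-values."""
    for p in (p_alpha, p_beta):
        if not 0.0 <= p <= 1.0:
            raise ValueError("p-values must lie in [0, 1]")
    return max(p_alpha, p_beta)


def bonferroni_adjust(p_raw: float, m: int) -> float:
    """min(p_raw * m, 1) over m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(p_raw * m, 1.0)


def run_mediation_tests(data: SurvivalDataset, refit: CoxFit,
                   mediator_fits: Sequence[MediatorFit],
                   alpha_level: float = 0.05) -> MediationResult:
    """Sobel and joint tests for every mediator in the refit, Bonferroni-
    adjusted over |S2| per the selected-set multiplicity rule."""
    S2 = list(refit.mediator_cols)
    m = max(len(S2), 1)
    fits = {f.mediator: f for f in mediator_fits}
    rows = []
    for j, k in enumerate(S2):
        mf = fits[k]
        beta_hat = float(refit.coefficients[refit.n_fixed + j])
        se_beta = float(refit.standard_errors[refit.n_fixed + j])
        sobel_se, z, p_sobel = sobel_test(mf.alpha_hat, mf.se_alpha, beta_hat, se_beta)
        if se_beta > 0:
            p_beta = float(2.0 * stats.norm.sf(abs(beta_hat) / se_beta))
        else:
            p_beta = 0.0 if beta_hat != 0 else 1.0
        p_joint = joint_test(mf.p_alpha, p_beta)
        rows.append({
            "mediator": int(k),
            "mediator_id": str(data.mediator_ids[k]),
            "alpha_hat": mf.alpha_hat, "se_alpha": mf.se_alpha,
            "beta_hat": beta_hat, "se_beta": se_beta,
            "indirect_log_hr": mf.alpha_hat * beta_hat,
            "sobel_se": sobel_se,
            "p_alpha": mf.p_alpha, "p_beta": p_beta,
            "p_sobel_raw": p_sobel,
            "p_sobel_adj": bonferroni_adjust(p_sobel, m),
            "p_joint_raw": p_joint,
            "p_joint_adj": bonferroni_adjust(p_joint, m),
        })
    cols = ["mediator_id", "alpha_hat", "se_alpha", "beta_hat", "se_beta",
            "indirect_log_hr", "sobel_se", "p_alpha", "p_beta", "p_sobel_raw",
            "p_sobel_adj", "p_joint_raw", "p_joint_adj"]
    table = pd.DataFrame(rows, columns=["mediator"] + cols).set_index("mediator") \
        if rows else pd.DataFrame(columns=cols, index=pd.Index([], name="mediator"))
    table["significant_sobel"] = table.get("p_sobel_adj", pd.Series(dtype=float)) < alpha_level
    table["significant_joint"] = table.get("p_joint_adj", pd.Series(dtype=float)) < alpha_level
    return MediationResult(table=table, alpha_level=alpha_level)


def decompose_effects(gamma_hat: float, gamma_se: float,
                      mediator_fits: Sequence[MediatorFit], refit: CoxFit,
                      x_from: float = 0.0, x_to: float = 1.0,
                      mediator_labels: Mapping[int, str] | None = None) -> EffectDecomposition:
    """Direct, per-mediator indirect, and total effects for x_from -> x_to.

    The total equals direct + sum(indirect) exactly on the log-HR scale.
    CIs: the direct effect uses the Cox SE of gamma_hat; each indirect
    effect uses its Sobel SE (normal on the log scale, endpoints
    exponentiated); the total-effect variance sums the components,
    treating them as independent.
    """
    dx = x_to - x_from
    fits = {f.mediator: f for f in mediator_fits}
    S2 = list(refit.mediator_cols)
    indirect: dict[int, float] = {}
    ind_se: dict[int, float] = {}
    var_total = (dx * gamma_se) ** 2
    sigma2_W = 0.0
    for j, k in enumerate(S2):
        mf = fits[k]
        beta_hat = float(refit.coefficients[refit.n_fixed + j])
        se_beta = float(refit.standard_errors[refit.n_fixed + j])
        se, _, _ = sobel_test(mf.alpha_hat, mf.se_alpha, beta_hat, se_beta)
        indirect[k] = dx * mf.alpha_hat * beta_hat
        ind_se[k] = abs(dx) * se
        var_total += (dx * se) ** 2
        sigma2_W += beta_hat**2 * mf.residual_variance
    direct = dx * gamma_hat
    total_indirect = math.fsum(indirect.values())
    return EffectDecomposition(
        x_from=x_from, x_to=x_to, direct_log_hr=direct,
        direct_se=abs(dx) * gamma_se, indirect_log_hr=indirect,
        indirect_se=ind_se, total_indirect_log_hr=total_indirect,
        total_log_hr=direct + total_indirect, total_se=math.sqrt(var_total),
        sigma2_W_beta=sigma2_W,
        mediator_labels=dict(mediator_labels or {}))


@dataclass
class CounterfactualParams:
    """Fitted parameter set for the marginalized counterfactual log hazard."""

    gamma: float
    theta: np.ndarray
    beta: np.ndarray              # over mediators, aligned with alpha/c/sigma2_M
    alpha: np.ndarray
    c: np.ndarray
    vartheta: np.ndarray
    sigma2_M: np.ndarray
    log_baseline: float = 0.0


def counterfactual_log_hazard(params: CounterfactualParams, x: float,
                              x_star: float, z: np.ndarray) -> float:
    """Approximate log hazard of T(x, M_1(x*), ..., M_p(x*)) given Z = z.

    log lambda_0(t) + theta'z + 1/2 sigma^2_{W beta}
      + sum_k beta_k (c_k + vartheta'z) + gamma x + (sum_k alpha_k beta_k) x*.

    Differencing two evaluations in x (mediator argument fixed) gives
    (x* - x) gamma; differencing in the mediator argument gives
    (x* - x) sum_k alpha_k beta_k — the baseline and variance terms cancel.
    """
    z = np.asarray(z, dtype=np.float64)
    sigma2_W = float(np.sum(params.beta**2 * params.sigma2_M))
    return float(
        params.log_baseline + params.theta @ z + 0.5 * sigma2_W
        + np.sum(params.beta * (params.c + params.vartheta @ z))
        + params.gamma * x + float(np.sum(params.alpha * params.beta)) * x_star)
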