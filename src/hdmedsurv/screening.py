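"""Sure independence screening (SIS) of candidate mediators.

Two marginal-ranking modes, both adjusting for exposure and covariates:

* ``outcome`` path — for each mediator k fit the marginal Cox model on
  (X, Z, M_k) and rank by the standardized coefficient |beta_hat_k| / SE;
* ``exposure`` path — fit the mediator regression
  M_k ~ 1 + X + Z by least squares and rank by |alpha_hat_k| / SE
  (used when mediator->outcome signals dominate exposure->mediator ones).

The retained set has size d = floor(multiplier * n / ln n) (capped at p),
with multiplier 2 by convention for outcome-path screening and 3 in
exposure-path applications.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .cox import NEWTON_MAXIT, NEWTON_TOL, fit_cox, sort_structure
from .datasets import SurvivalDataset
from .exceptions import DegenerateExposureError, NoEventsError

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    """Screened mediator set, ordered by descending ranking utility."""

    retained: np.ndarray          # mediator indices, best first
    d: int
    utilities: np.ndarray         # per-mediator ranking statistic (length p)
    mode: str

    def __contains__(self, k: int) -> bool:
        return int(k) in set(self.retained.tolist())


def screen_size(n: int, multiplier: float = 2.0) -> int:
    """d = floor(multiplier * n / ln n); requires n >= 3."""
    if n < 3:
        raise ValueError("need n >= 3 for a meaningful n/log(n) screen size")
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    return int(math.floor(multiplier * n / math.log(n)))


def _rank_top(utilities: np.ndarray, d: int) -> np.ndarray:
    # ties broken by lower mediator index (lexsort is stable on the index)
    p = utilities.shape[0]
    order = np.lexsort((np.arange(p), -utilities))
    return order[: min(d, p)]


def sis_outcome(data: SurvivalDataset, d: int) -> ScreenResult:
    """Outcome-path screening by marginal Cox association.

    A mediator whose marginal fit fails (e.g. a constant column) gets
    utility 0 with a logged warning rather than aborting the screen.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if data.n_events == 0:
        raise NoEventsError("no events")
    base = fit_cox(data)  # (X, Z) only; warm-starts every marginal fit
    Pb, _ = data.design((), True, True)
    order, first, last = sort_structure(data.time)
    res = _kernels.marginal_cox_batch(
        np.ascontiguousarray(Pb[order]), np.ascontiguousarray(data.mediators[order]),
        data.event[order], first, base.coefficients, NEWTON_TOL, NEWTON_MAXIT)
    coef, se, status = res[:, 0], res[:, 1], res[:, 2]
    utilities = np.zeros(data.p)
    ok = (status == 0) & (se > 0)
    utilities[ok] = np.abs(coef[ok]) / se[ok]
    n_failed = int((~ok).sum())
    if n_failed:
        logger.warning("marginal Cox fit failed for %d mediators; utility set to 0",
                       n_failed)
    return ScreenResult(retained=_rank_top(utilities, d), d=min(d, data.p),
                        utilities=utilities, mode="outcome")


def sis_exposure(data: SurvivalDataset, d: int) -> ScreenResult:
    """Exposure-path screening by the standardized OLS exposure coefficient.

    Fits M_k = c_k + alpha_k X + vartheta' Z + e_k for every mediator in one
    vectorized least-squares solve and ranks by |alpha_hat_k| / SE.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if np.ptp(data.exposure) == 0:
        raise DegenerateExposureError("degenerate exposure")
    n = data.n
    D = np.column_stack([np.ones(n), data.exposure, data.covariates])
    k = D.shape[1]
    G = D.T @ D
    Ginv = np.linalg.pinv(G)
    coefs = Ginv @ (D.T @ data.mediators)          # (k, p)
    resid = data.mediators - D @ coefs
    dof = n - k
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se_alpha = np.sqrt(np.clip(sigma2 * Ginv[1, 1], 0.0, None))
    utilities = np.zeros(data.p)
    ok = se_alpha > 0
    utilities[ok] = np.abs(coefs[1, ok]) / se_alpha[ok]
    n_failed = int((~ok).sum())
    if n_failed:
        logger.warning("zero residual variance for %d mediators; utility set to 0",
                       n_failed)
    return ScreenResult(retained=_rank_top(utilities, d), d=min(d, data.p),
                        utilities=utilities, mode="exposure")
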