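"""Synthetic survival-mediation data under an exponential-hazard model.

The generator emulates the validation study's design: a binary exposure
X ~ B(1, 0.6); covariates Z1 ~ B(1, 0.3) (gender-like) and Z2 ~ U(0, 1)
(age-like); Gaussian mediators

    M_k = c_k + alpha_k X + vartheta_1 Z1 + vartheta_2 Z2 + e_k,
    c_k ~ U(0,1) per replicate, e_k ~ N(0, residual_sd^2);

event times from an exponential hazard

    lambda(t | X, Z, M) = baseline_rate * exp(gamma X + theta' Z + beta' M);

and independent right-censoring C ~ U(0, c0), with c0 calibrated so the
expected censoring fraction hits a target. Under the default coefficient
pattern (alpha nonzero on mediators 1-6, beta nonzero on 1-4 and 7-8) there
are exactly 4 true mediators, i.e. indices with alpha_k * beta_k != 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .datasets import SurvivalDataset

_ALPHA8 = (0.5, 0.45, 0.5, 0.4, 0.45, 0.45, 0.0, 0.0)
_BETA8 = (0.55, 0.6, 0.65, 0.7, 0.0, 0.0, 0.5, 0.5)


def _default_pattern(p: int, head) -> np.ndarray:
    out = np.zeros(p)
    out[: min(p, len(head))] = head[: min(p, len(head))]
    return out


@dataclass
class SimulationConfig:
    """All generative parameters of the simulation design.

    Defaults reproduce the study conditions: exposure effect gamma = 0.5,
    covariate effects theta = (0.3, -0.2) on the hazard and
    vartheta = (0.3, 0.2) on the mediators, baseline hazard rate 0.5, unit
    mediator residual SD, and the 8-mediator nonzero coefficient head
    alpha = (0.5, 0.45, 0.5, 0.4, 0.45, 0.45, 0, 0),
    beta  = (0.55, 0.6, 0.65, 0.7, 0, 0, 0.5, 0.5).
    """

    n: int
    p: int
    gamma: float = 0.5
    theta: tuple[float, float] = (0.3, -0.2)
    alpha: np.ndarray | None = None
    beta: np.ndarray | None = None
    vartheta: tuple[float, float] = (0.3, 0.2)
    baseline_rate: float = 0.5
    residual_sd: float = 1.0
    censor_target: float = 0.15
    c0: float | str = "auto"
    seed: int = 0
    mediator_correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha is None:
            self.alpha = _default_pattern(self.p, _ALPHA8)
        else:
            self.alpha = np.asarray(self.alpha, dtype=np.float64)
        if self.beta is None:
            self.beta = _default_pattern(self.p, _BETA8)
        else:
            self.beta = np.asarray(self.beta, dtype=np.float64)
        if self.alpha.shape != (self.p,) or self.beta.shape != (self.p,):
            raise ValueError("alpha and beta must have length p")
        if not (0.0 <= self.censor_target < 1.0):
            raise ValueError("censor_target must be in [0, 1)")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if not (0.0 <= self.mediator_correlation < 1.0):
            raise ValueError("mediator_correlation must be in [0, 1)")

    @property
    def truth(self) -> np.ndarray:
        """Indices of true mediators, i.e. alpha_k * beta_k != 0."""
        return np.flatnonzero(self.alpha * self.beta != 0.0)

    def rng_for(self, replicate: int = 0) -> np.random.Generator:
        """Independent, individually reproducible stream per replicate."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed) % (2**31),
                                   spawn_key=(int(replicate),)))


@dataclass
class SelectionScore:
    """TPR / FP count / FDP for one selected set against the truth."""

    tpr: float
    fp: int
    fdp: float
    truth_empty: bool = False


def _draw_components(config: SimulationConfig, rng: np.random.Generator):
    n, p = config.n, config.p
    X = (rng.uniform(size=n) < 0.6).astype(np.float64)
    Z1 = (rng.uniform(size=n) < 0.3).astype(np.float64)
    Z2 = rng.uniform(size=n)
    c = rng.uniform(size=p)
    e = rng.normal(scale=config.residual_sd, size=(n, p))
    M = (c[None, :] + X[:, None] * config.alpha[None, :]
         + config.vartheta[0] * Z1[:, None] + config.vartheta[1] * Z2[:, None] + e)
    rho = config.mediator_correlation
    if rho > 0.0:
        # dependent-mediator variant: M~_k = M_k + sum_{l<k} rho^(k-l) M_l,
        # computed by the recursion S_k = rho (M_{k-1} + S_{k-1})
        S = np.zeros(n)
        Mdep = M.copy()
        for k in range(1, p):
            S = rho * (M[:, k - 1] + S)
            Mdep[:, k] = M[:, k] + S
        M = Mdep
    eta = (config.gamma * X + config.theta[0] * Z1 + config.theta[1] * Z2
           + M @ config.beta)
    rate = config.baseline_rate * np.exp(eta)
    D = rng.exponential(size=n) / rate  # exact inversion for the exponential hazard
    return X, Z1, Z2, M, D


def simulate_dataset(config: SimulationConfig, *, replicate: int = 0,
                     rng: np.random.Generator | None = None,
                     c0: float | None = None) -> tuple[SurvivalDataset, np.ndarray]:
    """One replicate of the generative model.

    Returns ``(dataset, truth)`` with ``truth`` the indices of mediators
    whose indirect-path product ``alpha_k * beta_k`` is nonzero. The
    censoring bound ``c0`` is taken from the argument, the config, or
    calibrated automatically to ``censor_target``.
    """
    if rng is None:
        rng = config.rng_for(replicate)
    no_censoring = c0 is None and config.c0 == "auto" and config.censor_target == 0.0
    if c0 is None and not no_censoring:
        c0 = config.c0 if config.c0 != "auto" else calibrate_c0(config, config.censor_target)
    X, Z1, Z2, M, D = _draw_components(config, rng)
    if no_censoring:
        C = np.full(config.n, np.inf)
    else:
        C = rng.uniform(0.0, float(c0), size=config.n)
    T = np.minimum(D, C)
    event = (D <= C).astype(np.float64)
    data = SurvivalDataset(time=T, event=event, exposure=X,
                           covariates=np.column_stack([Z1, Z2]), mediators=M,
                           covariate_names=["z1", "z2"])
    return data, config.truth


def calibrate_c0(config: SimulationConfig, target: float | None = None, *,
                 n_replicates: int = 50, seed: int | None = None) -> float:
    """Censoring bound c0 giving an expected censoring fraction ``target``.

    With C ~ U(0, c0) independent of the event time D, the probability of
    censoring given D is min(D / c0, 1); the calibration averages this over
    ``n_replicates`` simulated event-time replicates (Monte-Carlo mean over
    subjects) and solves for c0 by Brent's method. Deterministic given the
    calibration seed (config.seed + a fixed offset by default, so the
    calibration stream never overlaps the data streams).
    """
    if target is None:
        target = config.censor_target
    if not (0.0 < target < 1.0):
        raise ValueError("target censoring fraction must be in (0, 1)")
    if seed is None:
        seed = (int(config.seed) + 987_654_321) % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    # mediators with beta_k = 0 do not enter the hazard, so the event-time
    # distribution is unchanged if the mediator block is truncated past the
    # last nonzero beta; this keeps calibration cheap at large p
    nz = np.flatnonzero(config.beta)
    p_eff = int(nz.max()) + 1 if nz.size else 1
    p_eff = min(config.p, max(p_eff, 8))
    cfg_small = config if config.p == p_eff else replace(
        config, p=p_eff, alpha=config.alpha[:p_eff], beta=config.beta[:p_eff])
    draws = [_draw_components(cfg_small, rng)[4] for _ in range(n_replicates)]
    D = np.concatenate(draws)

    def expected_censoring(c0: float) -> float:
        return float(np.mean(np.minimum(D / c0, 1.0)))

    lo, hi = 1e-8, 1.0
    while expected_censoring(hi) > target:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError(f"censoring target {target} unreachable")
    return float(brentq(lambda c: expected_censoring(c) - target, lo, hi,
                        xtol=1e-10, rtol=1e-12))


def score_selection(selected, truth, p: int) -> SelectionScore:
    """TPR = |sel ∩ truth| / |truth|, FP = |sel \\ truth|, FDP = FP / |sel|.

    Conventions: FDP := 0 for an empty selection; an empty truth set flags
    the score (TPR undefined) with ``truth_empty=True``.
    """
    selected = set(int(i) for i in selected)
    truth = set(int(i) for i in truth)
    if not selected.issubset(range(p)) or not truth.issubset(range(p)):
        raise ValueError("indices must lie in [0, p)")
    fp = len(selected - truth)
    fdp = fp / len(selected) if selected else 0.0
    if not truth:
        return SelectionScore(tpr=float("nan"), fp=fp, fdp=fdp, truth_empty=True)
    tpr = len(selected & truth) / len(truth)
    return SelectionScore(tpr=tpr, fp=fp, fdp=fdp)
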