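"""End-to-end workflow: screen -> select -> test -> decompose.

Also provides the two baseline comparators (one-step penalized selection
without screening; the naive per-mediator marginal analysis) and the
replicate-level simulation experiment that reproduces the validation
study's selection-accuracy and estimation summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import _kernels
from ._version import __version__ as _pkg_version
from .cox import NEWTON_MAXIT, NEWTON_TOL, fit_cox, sort_structure
from .datasets import SurvivalDataset, read_dataset
from .inference import (EffectDecomposition, MediationResult, bonferroni_adjust,
                        decompose_effects, fit_mediator_model, sobel_test,
                        run_mediation_tests)
from .penalized import PenaltyConfig, SelectionResult, select_mediators
from .screening import ScreenResult, screen_size, sis_exposure, sis_outcome
from .simulate import SimulationConfig, calibrate_c0, score_selection, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one analysis run.

    Exactly one of ``simulation`` or the (``phenotype``, ``mediators``) file
    pair must be provided.
    """

    simulation: SimulationConfig | None = None
    phenotype: str | None = None
    mediators: str | None = None
    time_col: str = "time"
    event_col: str = "event"
    exposure_col: str = "exposure"
    covariate_cols: Sequence[str] | None = None
    screen_mode: str = "outcome"            # "outcome" | "exposure"
    screen_multiplier: float = 2.0
    penalty: PenaltyConfig = field(default_factory=PenaltyConfig)
    test: str = "both"                      # "sobel" | "joint" | "both"
    alpha_level: float = 0.05
    contrast: tuple[float, float] = (0.0, 1.0)
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        has_sim = self.simulation is not None
        has_files = self.phenotype is not None and self.mediators is not None
        if has_sim == has_files:
            raise ValueError("provide exactly one of a simulation block or input files")
        if self.screen_mode not in ("outcome", "exposure"):
            raise ValueError(f"unknown screen mode {self.screen_mode!r}")
        if self.test not in ("sobel", "joint", "both"):
            raise ValueError(f"unknown test {self.test!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        pen = raw.pop("penalty", {})
        if "contrast" in raw:
            raw["contrast"] = tuple(raw["contrast"])
        return cls(simulation=SimulationConfig(**sim) if sim else None,
                   penalty=PenaltyConfig(**pen), **raw)


@dataclass
class PipelineResult:
    data: SurvivalDataset
    screen: ScreenResult
    selection: SelectionResult
    mediation: MediationResult
    decomposition: EffectDecomposition
    marginal_total_log_hr: float
    marginal_total_se: float
    metadata: dict

    def write(self, out_dir) -> None:
        """Results TSV, decomposition JSON, and run-metadata JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table = self.mediation.table.copy()
        hr = np.exp(table["indirect_log_hr"])
        z = stats.norm.ppf(0.975)
        table["hr_indirect"] = hr
        table["hr_ci_low"] = np.exp(table["indirect_log_hr"] - z * table["sobel_se"])
        table["hr_ci_high"] = np.exp(table["indirect_log_hr"] + z * table["sobel_se"])
        table.to_csv(out / "results.tsv", sep="\t", float_format="%.10g")
        decomp = {
            "contrast": [self.decomposition.x_from, self.decomposition.x_to],
            "effects": json.loads(self.decomposition.hr_table().to_json(orient="index")),
            "sigma2_W_beta": self.decomposition.sigma2_W_beta,
            "marginal_total_log_hr": self.marginal_total_log_hr,
            "marginal_total_hr": math.exp(self.marginal_total_log_hr),
        }
        (out / "decomposition.json").write_text(json.dumps(decomp, indent=2, sort_keys=True))
        (out / "run_metadata.json").write_text(json.dumps(self.metadata, indent=2,
                                                          sort_keys=True, default=str))


def _load_data(config: RunConfig) -> tuple[SurvivalDataset, np.ndarray | None]:
    if config.simulation is not None:
        return simulate_dataset(config.simulation)
    data = read_dataset(config.phenotype, config.mediators,
                        time_col=config.time_col, event_col=config.event_col,
                        exposure_col=config.exposure_col,
                        covariate_cols=config.covariate_cols)
    return data, None


def run_pipeline(config: RunConfig, data: SurvivalDataset | None = None) -> PipelineResult:
    """Execute screening -> penalized selection -> refit -> tests -> decomposition.

    An empty selected set S2 is a valid outcome: the run reports no
    mediators with direct/total effects from the exposure-plus-covariates
    model only.
    """
    if data is None:
        data, _ = _load_data(config)
    d = screen_size(data.n, config.screen_multiplier)
    screen = (sis_outcome if config.screen_mode == "outcome" else sis_exposure)(data, d)
    logger.info("screening: |S1| = %d of p = %d (mode=%s)", len(screen.retained),
                data.p, config.screen_mode)
    selection = select_mediators(data, screen.retained, config.penalty)
    logger.info("selection: |S2| = %d at lambda = %.5g", len(selection.S2),
                selection.lambda_chosen)
    if len(selection.S2) == 0:
        logger.info("no mediators selected")
    med_fits = [fit_mediator_model(data, int(k)) for k in selection.S2]
    mediation = run_mediation_tests(data, selection.refit, med_fits, config.alpha_level)
    labels = {int(k): str(data.mediator_ids[k]) for k in selection.S2}
    decomposition = decompose_effects(
        selection.refit.coefficients[0], selection.refit.standard_errors[0],
        med_fits, selection.refit, x_from=config.contrast[0],
        x_to=config.contrast[1], mediator_labels=labels)
    marginal = fit_cox(data)  # total exposure effect without mediators, for comparison
    n_sig = {t: len(mediation.significant(t)) for t in ("sobel", "joint")}
    logger.info("significant mediators: sobel=%d joint=%d", n_sig["sobel"], n_sig["joint"])
    metadata = {
        "package_version": _pkg_version,
        "python": platform.python_version(),
        "seed": config.seed,
        "n": data.n, "p": data.p, "q": data.q, "n_events": data.n_events,
        "screen_mode": config.screen_mode, "screen_multiplier": config.screen_multiplier,
        "d": d, "S1_size": len(screen.retained), "S2_size": len(selection.S2),
        "penalty": dataclasses.asdict(config.penalty) | {
            "lambda_grid": "auto" if isinstance(config.penalty.lambda_grid, str)
            else list(map(float, np.atleast_1d(config.penalty.lambda_grid)))},
        "lambda_chosen": selection.lambda_chosen,
        "alpha_level": config.alpha_level,
        "contrast": list(config.contrast),
        "n_significant": n_sig,
    }
    result = PipelineResult(data=data, screen=screen, selection=selection,
                            mediation=mediation, decomposition=decomposition,
                            marginal_total_log_hr=float(marginal.coefficients[0]),
                            marginal_total_se=float(marginal.standard_errors[0]),
                            metadata=metadata)
    if config.out_dir:
        result.write(config.out_dir)
    return result


def run_baseline_naive(data: SurvivalDataset, alpha_level: float = 0.05) -> pd.DataFrame:
    """Naive per-mediator analysis over all p candidates, no selection.

    For every mediator: marginal Cox (X, Z, M_k) for beta_hat_k and the OLS
    mediator model for alpha_hat_k, then the Sobel and joint tests with a
    Bonferroni factor of p (the full number of candidates).
    """
    base = fit_cox(data)
    Pb, _ = data.design((), True, True)
    order, first, last = sort_structure(data.time)
    res = _kernels.marginal_cox_batch(
        np.ascontiguousarray(Pb[order]), np.ascontiguousarray(data.mediators[order]),
        data.event[order], first, base.coefficients, NEWTON_TOL, NEWTON_MAXIT)
    n = data.n
    D = np.column_stack([np.ones(n), data.exposure, data.covariates])
    G = np.linalg.pinv(D.T @ D)
    ols = G @ (D.T @ data.mediators)
    resid = data.mediators - D @ ols
    dof = n - D.shape[1]
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se_alpha = np.sqrt(np.clip(sigma2 * G[1, 1], 0.0, None))
    rows = []
    for k in range(data.p):
        beta_hat, se_beta, status = res[k]
        if status != 0 or se_beta <= 0:
            beta_hat, se_beta, p_beta = 0.0, 0.0, 1.0
        else:
            p_beta = float(2.0 * stats.norm.sf(abs(beta_hat) / se_beta))
        a_hat, se_a = float(ols[1, k]), float(se_alpha[k])
        p_a = float(2.0 * stats.t.sf(abs(a_hat) / se_a, dof)) if se_a > 0 else 1.0
        sobel_se, _, p_sobel = sobel_test(a_hat, se_a, float(beta_hat), float(se_beta))
        rows.append({
            "mediator": k, "mediator_id": str(data.mediator_ids[k]),
            "alpha_hat": a_hat, "se_alpha": se_a,
            "beta_hat": float(beta_hat), "se_beta": float(se_beta),
            "indirect_log_hr": a_hat * float(beta_hat), "sobel_se": sobel_se,
            "p_sobel_raw": p_sobel,
            "p_sobel_adj": bonferroni_adjust(p_sobel, data.p),
            "p_joint_raw": max(p_a, p_beta),
            "p_joint_adj": bonferroni_adjust(max(p_a, p_beta), data.p),
        })
    table = pd.DataFrame(rows).set_index("mediator")
    table["significant_sobel"] = table["p_sobel_adj"] < alpha_level
    table["significant_joint"] = table["p_joint_adj"] < alpha_level
    return table


def run_baseline_onestep(data: SurvivalDataset,
                         penalty: PenaltyConfig | None = None,
                         alpha_level: float = 0.05) -> tuple[SelectionResult, MediationResult]:
    """One-step comparator: penalized selection on all p mediators, no screening."""
    if data.p > 50_000:
        raise ValueError(
            f"one-step selection over p = {data.p} mediators is infeasible in "
            "memory; screen first (run_pipeline) or chunk the mediator matrix")
    selection = select_mediators(data, np.arange(data.p), penalty or PenaltyConfig())
    med_fits = [fit_mediator_model(data, int(k)) for k in selection.S2]
    mediation = run_mediation_tests(data, selection.refit, med_fits, alpha_level)
    return selection, mediation


@dataclass
class ExperimentReport:
    """Aggregated selection and estimation summaries over replicates.

    ``selection`` rows: one per (scenario, test) with the mean TPR, mean FP
    count, mean per-replicate FDP (0/0 := 0) plus the pooled variant
    sum(V)/sum(R), and Monte-Carlo SEs. ``estimation`` rows: one per
    (scenario, tracked mediator) with the mean estimate of alpha_k beta_k,
    empirical SE, mean estimated (Sobel) SE and 95% CI coverage over the
    replicates in which the mediator was selected.
    """

    selection: pd.DataFrame
    estimation: pd.DataFrame
    replicates: int
    failures: list[dict] = field(default_factory=list)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.selection.to_csv(out / "selection_report.tsv", sep="\t", index=False,
                              float_format="%.6g")
        self.estimation.to_csv(out / "estimation_report.tsv", sep="\t", index=False,
                               float_format="%.6g")


def _significant_sets(method: str, data: SurvivalDataset, run_cfg: RunConfig):
    if method == "pipeline":
        result = run_pipeline(run_cfg, data=data)
        med, sel = result.mediation, result.selection
        return (med.significant("sobel"), med.significant("joint"), med.table, sel.S2)
    if method == "onestep":
        sel, med = run_baseline_onestep(data, run_cfg.penalty, run_cfg.alpha_level)
        return (med.significant("sobel"), med.significant("joint"), med.table, sel.S2)
    if method == "naive":
        table = run_baseline_naive(data, run_cfg.alpha_level)
        sob = table.index[table["significant_sobel"]].to_numpy()
        joi = table.index[table["significant_joint"]].to_numpy()
        return sob, joi, table, table.index.to_numpy()
    raise ValueError(f"unknown method {method!r}")


def run_experiment(scenarios: Sequence[dict], replicates: int = 100, *,
                   p: int = 2000, seed: int = 0, method: str = "pipeline",
                   penalty: PenaltyConfig | None = None,
                   alpha_level: float = 0.05,
                   track_mediators: Sequence[int] | None = None,
                   sim_kwargs: dict | None = None) -> ExperimentReport:
    """Replicate-level simulation experiment over (n, censoring) scenarios.

    Each scenario dict needs ``n`` and ``censoring``; the censoring bound
    c0 is calibrated once per scenario with a dedicated stream, and each
    replicate draws from an independent, individually reproducible stream.
    Failed replicates are logged with their seed path and excluded.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    penalty = penalty or PenaltyConfig()
    sel_rows, est_rows, failures = [], [], []
    for si, scen in enumerate(scenarios):
        n, cen = int(scen["n"]), float(scen["censoring"])
        cfg = SimulationConfig(n=n, p=p, censor_target=cen,
                               seed=(seed * 1009 + si) % (2**31),
                               **(sim_kwargs or {}))
        c0 = calibrate_c0(cfg, cen)
        truth = cfg.truth
        if track_mediators is None:
            tracked = np.flatnonzero((cfg.alpha != 0) | (cfg.beta != 0))
        else:
            tracked = np.asarray(track_mediators, dtype=np.int64)
        per_test: dict[str, dict[str, list]] = {
            t: {"tpr": [], "fp": [], "fdp": []} for t in ("sobel", "joint")}
        est: dict[int, dict[str, list]] = {
            int(k): {"est": [], "se": [], "cover": []} for k in tracked}
        done = 0
        for r in range(replicates):
            try:
                data, _ = simulate_dataset(cfg, replicate=r, c0=c0)
                run_cfg = RunConfig(simulation=cfg, penalty=penalty,
                                    alpha_level=alpha_level, seed=cfg.seed)
                sig_sobel, sig_joint, table, S2 = _significant_sets(method, data, run_cfg)
            except Exception as exc:  # noqa: BLE001 - replicate isolation
                logger.warning("replicate failed (scenario %d, replicate %d, "
                               "seed %d): %s", si, r, cfg.seed, exc)
                failures.append({"scenario": si, "replicate": r,
                                 "seed": cfg.seed, "error": repr(exc)})
                continue
            done += 1
            for tname, sig in (("sobel", sig_sobel), ("joint", sig_joint)):
                sc = score_selection(sig, truth, p)
                per_test[tname]["tpr"].append(sc.tpr)
                per_test[tname]["fp"].append(sc.fp)
                per_test[tname]["fdp"].append(sc.fdp)
            z95 = 1.959963984540054
            for k in tracked:
                if int(k) in table.index:
                    row = table.loc[int(k)]
                    estimate, se = float(row["indirect_log_hr"]), float(row["sobel_se"])
                    true_prod = float(cfg.alpha[k] * cfg.beta[k])
                    est[int(k)]["est"].append(estimate)
                    est[int(k)]["se"].append(se)
                    est[int(k)]["cover"].append(
                        abs(estimate - true_prod) <= z95 * se)
        for tname, acc in per_test.items():
            tpr = np.asarray(acc["tpr"], dtype=float)
            fp = np.asarray(acc["fp"], dtype=float)
            fdp = np.asarray(acc["fdp"], dtype=float)
            pooled_sel = fp.sum() + tpr.sum() * len(truth)
            sel_rows.append({
                "scenario": si, "n": n, "censoring": cen, "method": method,
                "test": tname, "replicates": done,
                "tpr": float(tpr.mean()) if done else math.nan,
                "tpr_mc_se": float(tpr.std(ddof=1) / math.sqrt(done)) if done > 1 else math.nan,
                "fp": float(fp.mean()) if done else math.nan,
                "fdp": float(fdp.mean()) if done else math.nan,
                "fdp_pooled": float(fp.sum() / pooled_sel) if pooled_sel > 0 else 0.0,
            })
        for k in tracked:
            e = np.asarray(est[int(k)]["est"], dtype=float)
            s = np.asarray(est[int(k)]["se"], dtype=float)
            cov = np.asarray(est[int(k)]["cover"], dtype=float)
            est_rows.append({
                "scenario": si, "n": n, "censoring": cen, "method": method,
                "mediator": int(k),
                "true_product": float(cfg.alpha[k] * cfg.beta[k]),
                "n_selected": int(e.size),
                "mean_est": float(e.mean()) if e.size else math.nan,
                "emp_se": float(e.std(ddof=1)) if e.size > 1 else math.nan,
                "mean_se": float(s.mean()) if s.size else math.nan,
                "coverage": float(cov.mean()) if cov.size else math.nan,
            })
    return ExperimentReport(selection=pd.DataFrame(sel_rows),
                            estimation=pd.DataFrame(est_rows),
                            replicates=replicates, failures=failures)
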