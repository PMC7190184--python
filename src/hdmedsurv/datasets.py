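"""The survival-mediation data container and file ingest.

A :class:`SurvivalDataset` holds, per subject, the observed follow-up time
``T_i = min(D_i, C_i)``, the event indicator ``delta_i = I(D_i <= C_i)``, a
binary exposure ``X_i``, ``q`` baseline covariates ``Z_i``, and a
``p``-vector of candidate mediators ``M_i`` (typically p >> n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import MissingMediatorError

logger = logging.getLogger(__name__)


def _as_labels(labels, n: int, prefix: str) -> np.ndarray:
    if labels is None:
        return np.array([f"{prefix}{i + 1}" for i in range(n)], dtype=object)
    out = np.asarray(labels, dtype=object)
    if out.shape != (n,):
        raise ValueError(f"expected {n} {prefix} labels, got {out.shape}")
    return out


@dataclass
class SurvivalDataset:
    """Per-subject survival outcome, exposure, covariates and mediator matrix.

    Parameters
    ----------
    time : (n,) array
        Observed follow-up time, ``min`` of event and censoring time; >= 0.
    event : (n,) array
        Event indicator in {0, 1} (1 = event observed).
    exposure : (n,) array
        Exposure of interest (binary in the motivating application).
    covariates : (n, q) array
        Baseline adjustment covariates.
    mediators : (n, p) array
        Candidate mediator matrix; must be complete (no NaN) — missingness
        is rejected at construction, imputation is out of scope.
    """

    time: np.ndarray
    event: np.ndarray
    exposure: np.ndarray
    covariates: np.ndarray
    mediators: np.ndarray
    subject_ids: np.ndarray | None = None
    mediator_ids: np.ndarray | None = None
    covariate_names: Sequence[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.time = np.ascontiguousarray(self.time, dtype=np.float64)
        self.event = np.ascontiguousarray(self.event, dtype=np.float64)
        self.exposure = np.ascontiguousarray(self.exposure, dtype=np.float64)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=np.float64))
        if self.covariates.shape[0] != self.time.shape[0] and self.covariates.shape[1] == self.time.shape[0]:
            self.covariates = self.covariates.T
        self.mediators = np.ascontiguousarray(self.mediators, dtype=np.float64)
        if self.mediators.ndim == 1:
            self.mediators = self.mediators[:, None]
        n = self.time.shape[0]
        if n < 10:
            raise ValueError(f"need at least 10 subjects, got {n}")
        for name, arr in (("event", self.event), ("exposure", self.exposure)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
        if self.covariates.shape[0] != n:
            raise ValueError("covariates row count does not match time")
        if self.mediators.shape[0] != n:
            raise ValueError("mediators row count does not match time")
        if self.mediators.shape[1] < 1:
            raise ValueError("need at least one mediator column")
        if np.any(self.time < 0) or not np.all(np.isfinite(self.time)):
            raise ValueError("times must be finite and nonnegative")
        if not np.all(np.isin(self.event, (0.0, 1.0))):
            raise ValueError("event indicator must be 0/1")
        if np.isnan(self.mediators).any():
            k = int(np.isnan(self.mediators).sum())
            raise MissingMediatorError(
                f"mediator matrix contains {k} missing values; impute or drop upstream"
            )
        self.subject_ids = _as_labels(self.subject_ids, n, "s")
        self.mediator_ids = _as_labels(self.mediator_ids, self.mediators.shape[1], "M")
        if self.covariate_names is None:
            self.covariate_names = [f"Z{j + 1}" for j in range(self.covariates.shape[1])]

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def p(self) -> int:
        return self.mediators.shape[1]

    @property
    def q(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def design(self, mediator_cols: Sequence[int] = (),
               include_exposure: bool = True,
               include_covariates: bool = True) -> tuple[np.ndarray, list[str]]:
        """Assemble a design matrix ``[X | Z | M[:, cols]]`` with column names."""
        blocks: list[np.ndarray] = []
        names: list[str] = []
        if include_exposure:
            blocks.append(self.exposure[:, None])
            names.append("exposure")
        if include_covariates and self.q > 0:
            blocks.append(self.covariates)
            names.extend(self.covariate_names)
        cols = list(mediator_cols)
        if cols:
            blocks.append(self.mediators[:, cols])
            names.extend(str(self.mediator_ids[c]) for c in cols)
        if not blocks:
            raise ValueError("empty design")
        return np.ascontiguousarray(np.column_stack(blocks)), names

    def n_fixed_columns(self, include_exposure: bool = True,
                        include_covariates: bool = True) -> int:
        return int(include_exposure) + (self.q if include_covariates else 0)


def read_dataset(phenotype_path, mediators_path, *, time_col: str = "time",
                 event_col: str = "event", exposure_col: str = "exposure",
                 covariate_cols: Sequence[str] | None = None,
                 sep: str | None = None) -> SurvivalDataset:
    """Read a phenotype table and a subjects-by-mediators matrix from TSV/CSV.

    The first column of the mediator table must be a subject id matching the
    phenotype table's ``subject_id`` column (or its first column). Subjects
    with missing survival time, event, exposure, or covariates are dropped
    (complete-case analysis) with a logged count; missing mediator values are
    an error.
    """
    kws = {"sep": sep} if sep is not None else {"sep": None, "engine": "python"}
    pheno = pd.read_csv(phenotype_path, **kws)
    med = pd.read_csv(mediators_path, **kws)
    id_col = "subject_id" if "subject_id" in pheno.columns else pheno.columns[0]
    pheno = pheno.set_index(id_col)
    med = med.set_index(med.columns[0])
    if covariate_cols is None:
        reserved = {time_col, event_col, exposure_col}
        covariate_cols = [c for c in pheno.columns if c not in reserved]
    needed = [time_col, event_col, exposure_col, *covariate_cols]
    missing = [c for c in needed if c not in pheno.columns]
    if missing:
        raise KeyError(f"phenotype table lacks columns: {missing}")
    common = pheno.index.intersection(med.index)
    pheno = pheno.loc[common, needed]
    n_before = len(pheno)
    pheno = pheno.dropna()
    n_dropped = n_before - len(pheno)
    if n_dropped:
        logger.info("complete-case filter dropped %d of %d subjects", n_dropped, n_before)
    med = med.loc[pheno.index]
    return SurvivalDataset(
        time=pheno[time_col].to_numpy(),
        event=pheno[event_col].to_numpy(),
        exposure=pheno[exposure_col].to_numpy(),
        covariates=pheno[list(covariate_cols)].to_numpy(),
        mediators=med.to_numpy(),
        subject_ids=pheno.index.to_numpy(dtype=object),
        mediator_ids=med.columns.to_numpy(dtype=object),
        covariate_names=list(covariate_cols),
    )
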