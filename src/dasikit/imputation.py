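"""Multiple-imputation sensitivity analysis.

Chained-equations imputation — predictive mean matching (PMM) for numeric
covariates, proportional draws from the observed distribution for categorical
ones — produces ``m`` completed cohorts (default 20). The final multivariable
Cox model is refit on each, and the focal covariate's hazard ratio is
summarized two ways: the min-max range across the m fits (the primary,
assumption-light summary) and the Rubin's-rules pooled estimate (pooled
coefficient with within+between variance).

The survival outcome (time, event) is never imputed; it serves as a predictor
(log time and the event indicator) in every imputation model. Observed cells
are never modified, and runs are bit-reproducible given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .survival import CovariateSpec, CoxFit, Z_95, _expand_design, cox_fit

PMM_DONORS = 5
DEFAULT_CYCLES = 10


def _predictor_matrix(work: pd.DataFrame, cols: Sequence[str], exclude: str) -> np.ndarray:
    """Numeric design from every covariate except ``exclude``, plus outcome."""
    pieces = [np.ones((len(work), 1))]
    for c in cols:
        if c == exclude:
            continue
        col = work[c]
        if pd.api.types.is_numeric_dtype(col):
            pieces.append(col.to_numpy(dtype=float)[:, None])
        else:
            dummies = pd.get_dummies(col.astype(str), drop_first=True)
            if dummies.shape[1]:
                pieces.append(dummies.to_numpy(dtype=float))
    pieces.append(np.log(work["survival_time"].to_numpy(dtype=float))[:, None])
    pieces.append(work["event"].to_numpy(dtype=float)[:, None])
    return np.hstack(pieces)


def _impute_once(df: pd.DataFrame, covariates: Sequence[str], rng: np.random.Generator,
                 n_cycles: int) -> pd.DataFrame:
    work = df.copy()
    masks = {c: df[c].isna().to_numpy() for c in covariates if df[c].isna().any()}
    if not masks:
        return work
    for c, mask in masks.items():
        observed = df.loc[~mask, c]
        if observed.empty:
            raise ValidationError(f"covariate {c!r} is 100% missing; nothing to condition on")

    numeric = [c for c in masks if pd.api.types.is_numeric_dtype(df[c])]
    categorical = [c for c in masks if c not in numeric]

    # categorical: proportional draw from the observed level frequencies
    # (observed values donated as-is, so booleans stay booleans)
    for c in categorical:
        mask = masks[c]
        obs = df.loc[~mask, c]
        levels = obs.value_counts(normalize=True)
        draws = rng.choice(levels.index.to_numpy(), size=int(mask.sum()), p=levels.to_numpy())
        work.loc[mask, c] = draws

    # numeric: initial fill by random draws from the observed values
    for c in numeric:
        mask = masks[c]
        obs = df.loc[~mask, c].to_numpy(dtype=float)
        work.loc[mask, c] = rng.choice(obs, size=int(mask.sum()), replace=True)

    # chained PMM cycles
    for _ in range(n_cycles):
        for c in numeric:
            mask = masks[c]
            Xfull = _predictor_matrix(work, covariates, exclude=c)
            y_obs = df.loc[~mask, c].to_numpy(dtype=float)
            beta, *_ = np.linalg.lstsq(Xfull[~mask], y_obs, rcond=None)
            pred = Xfull @ beta
            pred_obs, pred_mis = pred[~mask], pred[mask]
            filled = np.empty(pred_mis.size)
            k = min(PMM_DONORS, y_obs.size)
            for i, pm in enumerate(pred_mis):
                donors = np.argpartition(np.abs(pred_obs - pm), k - 1)[:k]
                filled[i] = y_obs[donors[rng.integers(k)]]
            work.loc[mask, c] = filled
    return work


def impute(
    df: pd.DataFrame,
    covariates: Sequence[str],
    m: int = 20,
    seed: int = 0,
    n_cycles: int = DEFAULT_CYCLES,
) -> list[pd.DataFrame]:
    """Produce ``m`` completed copies of the analysis frame.

    Only missing cells among ``covariates`` are filled; a frame with no
    missing values comes back unchanged m times.
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    for c in covariates:
        if c not in df.columns:
            raise ValidationError(f"covariate column {c!r} absent from frame")
    return [
        _impute_once(df, covariates, np.random.default_rng([int(seed), k]), n_cycles)
        for k in range(m)
    ]


@dataclass(frozen=True)
class ImputationRun:
    """Per-dataset fits and the pooled summary for the focal covariate."""

    m: int
    seed: int
    focal_term: str
    fits: list[CoxFit]
    hr_per_dataset: np.ndarray
    p_per_dataset: np.ndarray
    pooled_coef: float
    pooled_se: float

    @property
    def hr_range(self) -> tuple[float, float]:
        return float(self.hr_per_dataset.min()), float(self.hr_per_dataset.max())

    @property
    def pooled_hr(self) -> float:
        return math.exp(self.pooled_coef)

    @property
    def pooled_ci(self) -> tuple[float, float]:
        return (
            math.exp(self.pooled_coef - Z_95 * self.pooled_se),
            math.exp(self.pooled_coef + Z_95 * self.pooled_se),
        )

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dataset": np.arange(1, self.m + 1),
             "hazard_ratio": self.hr_per_dataset,
             "p_value": self.p_per_dataset}
        )


def sensitivity_analysis(
    df: pd.DataFrame,
    model_specs: Sequence[CovariateSpec],
    focal: str,
    m: int = 20,
    seed: int = 0,
    n_cycles: int = DEFAULT_CYCLES,
    time_col: str = "survival_time",
    event_col: str = "event",
    ties: str = "efron",
) -> ImputationRun:
    """Refit the multivariable model on ``m`` imputed cohorts.

    ``model_specs`` are the covariates of the final model (the
    build_multivariable selection); ``focal`` names the covariate whose HR is
    tracked (its first design term for categoricals).
    """
    names = [s.name for s in model_specs]
    if focal not in names:
        raise ValidationError(f"focal covariate {focal!r} not in the model")
    columns = [s.column for s in model_specs]
    completed = impute(df, columns, m=m, seed=seed, n_cycles=n_cycles)

    fits: list[CoxFit] = []
    hrs, pvals, coefs, ses = [], [], [], []
    focal_term: Optional[str] = None
    for k, comp in enumerate(completed):
        designs = []
        for s in model_specs:
            d, _ = _expand_design(comp, s)
            designs.append(d)
        design = pd.concat(designs, axis=1)
        design = design[[c for c in design.columns if design[c].nunique() > 1]]
        try:
            fit = cox_fit(
                comp[time_col].to_numpy(dtype=float),
                comp[event_col].to_numpy(dtype=bool),
                design.to_numpy(dtype=float),
                names=list(design.columns),
                ties=ties,
            )
        except Exception as exc:
            raise ValidationError(f"model fit failed on imputed dataset {k}: {exc}") from exc
        if focal_term is None:
            focal_term = next(t for t in fit.names if t == focal or t.startswith(f"{focal}["))
        j = fit.names.index(focal_term)
        fits.append(fit)
        hrs.append(fit.hazard_ratio[j])
        pvals.append(fit.p_values[j])
        coefs.append(fit.coef[j])
        ses.append(fit.se[j])

    coefs = np.asarray(coefs)
    ses = np.asarray(ses)
    pooled_coef = float(coefs.mean())
    within = float(np.mean(ses**2))
    between = float(np.var(coefs, ddof=1)) if m > 1 else 0.0
    total_var = within + (1.0 + 1.0 / m) * between
    return ImputationRun(
        m=m, seed=int(seed), focal_term=focal_term, fits=fits,
        hr_per_dataset=np.asarray(hrs), p_per_dataset=np.asarray(pvals),
        pooled_coef=pooled_coef, pooled_se=math.sqrt(total_var),
    )
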