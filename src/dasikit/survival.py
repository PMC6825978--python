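"""Survival estimation and testing: Kaplan-Meier, log-rank, Cox regression,
the univariate screen / multivariable model-building rules, group comparison
tables, and the minimum-detectable-hazard-ratio power formula.

Time is measured in days from the index hospital admission; ``event`` is True
for an observed death and False for censoring at last follow-up.

The Cox partial likelihood is maximized by Newton-Raphson with analytic
gradient and Hessian, Efron tie handling by default (day-resolution survival
times make heavy ties the norm) or Breslow on request. Wald inference
throughout: HR = exp(beta), 95% CI = exp(beta +/- 1.96 se).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import qr as _qr_pivoted

from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times

from .errors import ConvergenceError, ValidationError

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# Samples and Kaplan-Meier estimation
# ---------------------------------------------------------------------------

def _as_sample(time, event):
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if t.ndim != 1 or t.size == 0:
        raise ValidationError("sample must contain at least one subject")
    if t.shape != e.shape:
        raise ValidationError("time and event must have equal length")
    if not np.all(np.isfinite(t)) or np.any(t <= 0):
        raise ValidationError("survival times must be finite and strictly positive")
    return t, e


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate with Greenwood variance and median CI.

    ``median`` and either CI bound are None when undetermined (the curve, or
    its confidence band, never reaches 0.5).
    """

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) at each event time
    variance: np.ndarray       # Greenwood variance of S(t)
    at_risk: np.ndarray
    events: np.ndarray
    median: Optional[float]
    median_ci: tuple[Optional[float], Optional[float]]
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_fit(time, event, alpha: float = 0.05) -> SurvivalCurve:
    """Kaplan-Meier curve with Greenwood variance and a Brookmeyer-Crowley
    style median CI from the log(-log) pointwise band."""
    t, e = _as_sample(time, event)
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(t, event_observed=e)
    tbl = kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    d = ev["observed"].to_numpy(dtype=float)
    n_at_risk = ev["at_risk"].to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    # Greenwood: Var S(t) = S(t)^2 * sum_{t_j <= t} d_j / (n_j (n_j - d_j))
    with np.errstate(divide="ignore", invalid="ignore"):
        incr = np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), np.inf)
    variance = surv**2 * np.cumsum(incr)
    variance = np.where(np.isfinite(variance), variance, 0.0)

    med = kmf.median_survival_time_
    median = None if math.isinf(med) else float(med)
    ci_df = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci_df.iloc[0, 0]), float(ci_df.iloc[0, 1])
    median_ci = (None if math.isinf(lo) else lo, None if math.isinf(hi) else hi)
    return SurvivalCurve(
        times=times, survival=surv, variance=variance,
        at_risk=n_at_risk, events=d.astype(int),
        median=median, median_ci=median_ci,
        n=int(t.size), n_events=int(e.sum()),
    )


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def logrank_test(samples: Sequence[tuple]) -> LogRankResult:
    """K-group log-rank chi-square test; ``samples`` is a sequence of
    (time, event) pairs, one per group."""
    if len(samples) < 2:
        raise ValidationError("log-rank test needs at least 2 groups")
    times, events, groups = [], [], []
    for g, (time, event) in enumerate(samples):
        t, e = _as_sample(time, event)
        times.append(t)
        events.append(e)
        groups.append(np.full(t.size, g))
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(groups), np.concatenate(events)
    )
    df = len(samples) - 1
    stat = float(res.test_statistic)
    return LogRankResult(statistic=stat, df=df, p_value=float(sps.chi2.sf(stat, df)))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxFit:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    ties: str
    n_iter: int
    converged: bool

    @property
    def hazard_ratio(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_lower(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.coef - Z_95 * self.se)

    @property
    def ci_upper(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.coef + Z_95 * self.se)

    @property
    def z(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * sps.norm.sf(np.abs(self.z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hazard_ratio": self.hazard_ratio,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p_value": self.p_values,
            },
            index=self.names,
        )


def _check_design(X: np.ndarray, names: Sequence[str]):
    if X.ndim != 2:
        raise ValidationError("covariate matrix must be 2-dimensional")
    n, p = X.shape
    if p == 0:
        raise ValidationError("at least one covariate required")
    const = [names[j] for j in range(p) if np.ptp(X[:, j]) == 0.0]
    if const:
        raise ValidationError(f"degenerate (constant) covariates: {const}")
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < p:
        # pivoted QR identifies which columns are linearly dependent
        _, _, piv = _qr_pivoted(Xc, pivoting=True, mode="economic")
        dependent = sorted(names[j] for j in piv[rank:])
        raise ValidationError(f"rank-deficient design; collinear columns: {dependent}")


def _partial_loglik(beta, t, e, X, ties):
    """Log partial likelihood with analytic gradient and Hessian.

    Arrays must be sorted by ascending time. Risk set at an event time t* is
    every subject with t >= t*.
    """
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # overflow guard; partial likelihood is shift-invariant up to a constant
    w = np.exp(eta)
    wX = w[:, None] * X
    wXX = np.einsum("i,ij,ik->ijk", w, X, X)
    # suffix sums: S0[i] = sum_{j >= i} w_j etc.
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]
    S2 = np.cumsum(wXX[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        deaths = np.arange(i, j)[e[i:j]]
        d = deaths.size
        if d > 0:
            R0, R1, R2 = S0[i], S1[i], S2[i]
            ll += float(eta[deaths].sum())
            grad += X[deaths].sum(axis=0)
            if ties == "breslow":
                ll -= d * math.log(R0)
                grad -= d * R1 / R0
                hess -= d * (R2 / R0 - np.outer(R1, R1) / R0**2)
            else:  # efron
                D0 = w[deaths].sum()
                D1 = wX[deaths].sum(axis=0)
                D2 = wXX[deaths].sum(axis=0)
                for l in range(d):
                    phi = l / d
                    E0 = R0 - phi * D0
                    E1 = R1 - phi * D1
                    E2 = R2 - phi * D2
                    ll -= math.log(E0)
                    grad -= E1 / E0
                    hess -= E2 / E0 - np.outer(E1, E1) / E0**2
        i = j
    return ll, grad, hess


def cox_fit(
    time,
    event,
    X,
    names: Optional[Sequence[str]] = None,
    ties: str = "efron",
    max_iter: int = 100,
    score_tol: float = 1e-6,
    ll_rel_tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Raises :class:`ConvergenceError` on a monotone likelihood (e.g. complete
    separation on a binary covariate) instead of returning a silently huge
    coefficient, and :class:`ValidationError` on a rank-deficient design,
    naming the collinear columns.
    """
    if ties not in ("efron", "breslow"):
        raise ValidationError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    t, e = _as_sample(time, event)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != t.size:
        raise ValidationError("covariate matrix and times must align")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    names = list(names)
    if e.sum() == 0:
        raise ValidationError("at least one event is required")
    _check_design(X, names)

    order = np.argsort(t, kind="stable")
    t, e, Xs = t[order], e[order], X[order]

    beta = np.zeros(X.shape[1])
    ll, grad, hess = _partial_loglik(beta, t, e, Xs, ties)
    ll_null = ll
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        info = -hess
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        # step-halving to guarantee ascent
        new_beta = beta + step
        new_ll, new_grad, new_hess = _partial_loglik(new_beta, t, e, Xs, ties)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = _partial_loglik(new_beta, t, e, Xs, ties)
            halvings += 1
        rel_change = abs(new_ll - ll) / max(1.0, abs(ll))
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.max(np.abs(beta)) > 20.0:
            raise ConvergenceError(
                "monotone partial likelihood (coefficient diverging); "
                "check for complete separation in a binary covariate"
            )
        if np.max(np.abs(grad)) < score_tol or rel_change < ll_rel_tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"Newton-Raphson did not converge in {max_iter} iterations")
    if np.max(np.abs(beta)) > 10.0:
        # the likelihood can flatten out numerically while a coefficient is
        # still drifting to +/- infinity; treat |log HR| > 10 as separation
        raise ConvergenceError(
            "monotone partial likelihood (coefficient diverging); "
            "check for complete separation in a binary covariate"
        )

    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    return CoxFit(
        names=names, coef=beta, se=se, loglik=ll, loglik_null=ll_null,
        n=int(t.size), n_events=int(e.sum()), ties=ties,
        n_iter=n_iter, converged=converged,
    )


def cox_score_test(time, event, X, ties: str = "breslow") -> tuple[float, int, float]:
    """Score (Rao) test of beta = 0: statistic, df, p-value.

    With Breslow ties, two groups and untied event times this reproduces the
    log-rank chi-square exactly.
    """
    t, e = _as_sample(time, event)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    order = np.argsort(t, kind="stable")
    t, e, Xs = t[order], e[order], X[order]
    _, grad, hess = _partial_loglik(np.zeros(X.shape[1]), t, e, Xs, ties)
    info = -hess
    stat = float(grad @ np.linalg.solve(info, grad))
    df = X.shape[1]
    return stat, df, float(sps.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Covariate registry, univariate screen and multivariable model building
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateSpec:
    """One analysis covariate: column, type and modelling transforms.

    ``kind`` is numeric | binary | categorical. Numeric covariates with
    ``log_transform`` enter the model as ln(x) (or ln(x+1) when
    ``log_plus_one``, for nonnegative quantities such as length of stay).
    Categorical covariates expand to indicator contrasts against
    ``reference``. ``collinear_group`` names a set of near-duplicate markers
    of which only the flagged ``representative`` enters multivariable models;
    ``forced`` covariates are included regardless of the screen.
    """

    name: str
    column: str
    kind: str = "numeric"
    log_transform: bool = False
    log_plus_one: bool = False
    reference: Optional[str] = None
    collinear_group: Optional[str] = None
    representative: bool = False
    forced: bool = False
    screen_only: bool = False

    def __post_init__(self):
        if self.kind not in ("numeric", "binary", "categorical"):
            raise ValidationError(f"covariate {self.name!r}: bad kind {self.kind!r}")
        if self.kind == "categorical" and self.reference is None:
            raise ValidationError(f"categorical covariate {self.name!r} needs a reference level")


def _expand_design(df: pd.DataFrame, spec: CovariateSpec):
    """Complete-case design columns for one covariate.

    Returns (design DataFrame indexed like df's complete cases, term names).
    """
    col = df[spec.column]
    mask = col.notna()
    sub = col[mask]
    if spec.kind == "numeric":
        x = sub.astype(float)
        if spec.log_transform:
            if spec.log_plus_one:
                x = np.log1p(x)
            else:
                if (x <= 0).any():
                    raise ValidationError(
                        f"covariate {spec.name!r}: log transform requires positive values"
                    )
                x = np.log(x)
        design = pd.DataFrame({spec.name: x})
        terms = [spec.name]
    elif spec.kind == "binary":
        design = pd.DataFrame({spec.name: sub.astype(float)})
        terms = [spec.name]
    else:
        levels = sorted(str(v) for v in sub.unique())
        if spec.reference in levels:
            levels.remove(spec.reference)
        terms = [f"{spec.name}[{lev}]" for lev in levels]
        design = pd.DataFrame(
            {f"{spec.name}[{lev}]": (sub.astype(str) == lev).astype(float) for lev in levels}
        )
    return design, terms


@dataclass
class ScreenResult:
    """Univariate screen output: per-term table plus the selection sets."""

    table: pd.DataFrame
    selected: list[str] = field(default_factory=list)
    degenerate: list[str] = field(default_factory=list)
    alpha: float = 0.05


def univariate_screen(
    df: pd.DataFrame,
    registry: Sequence[CovariateSpec],
    time_col: str = "survival_time",
    event_col: str = "event",
    alpha: float = 0.05,
    ties: str = "efron",
) -> ScreenResult:
    """One Cox model per covariate on complete cases; a covariate is selected
    when any of its Wald term p-values is below ``alpha``."""
    rows = []
    selected, degenerate = [], []
    for spec in registry:
        if spec.column not in df.columns:
            raise ValidationError(f"covariate column {spec.column!r} absent from cohort frame")
        design, terms = _expand_design(df, spec)
        idx = design.index
        time = df.loc[idx, time_col].to_numpy(dtype=float)
        event = df.loc[idx, event_col].to_numpy(dtype=bool)
        X = design.to_numpy(dtype=float)
        if X.shape[1] == 0 or any(np.ptp(X[:, j]) == 0.0 for j in range(X.shape[1])) or event.sum() == 0:
            degenerate.append(spec.name)
            rows.append(
                {"covariate": spec.name, "term": spec.name, "n": int(len(idx)),
                 "coef": np.nan, "hazard_ratio": np.nan, "ci_lower": np.nan,
                 "ci_upper": np.nan, "p_value": np.nan, "note": "degenerate covariate"}
            )
            continue
        try:
            fit = cox_fit(time, event, X, names=terms, ties=ties)
        except (ConvergenceError, ValidationError) as exc:
            degenerate.append(spec.name)
            rows.append(
                {"covariate": spec.name, "term": spec.name, "n": int(len(idx)),
                 "coef": np.nan, "hazard_ratio": np.nan, "ci_lower": np.nan,
                 "ci_upper": np.nan, "p_value": np.nan, "note": f"fit failed: {exc}"}
            )
            continue
        pvals = fit.p_values
        for k, term in enumerate(terms):
            rows.append(
                {"covariate": spec.name, "term": term, "n": fit.n,
                 "coef": fit.coef[k], "hazard_ratio": fit.hazard_ratio[k],
                 "ci_lower": fit.ci_lower[k], "ci_upper": fit.ci_upper[k],
                 "p_value": pvals[k], "note": ""}
            )
        if np.any(pvals < alpha):
            selected.append(spec.name)
    return ScreenResult(table=pd.DataFrame(rows), selected=selected,
                        degenerate=degenerate, alpha=alpha)


DEFAULT_MAX_COVARIATES = 13


def build_multivariable(
    df: pd.DataFrame,
    screen: ScreenResult,
    registry: Sequence[CovariateSpec],
    forced: Optional[Sequence[str]] = None,
    max_covariates: int = DEFAULT_MAX_COVARIATES,
    time_col: str = "survival_time",
    event_col: str = "event",
    ties: str = "efron",
) -> tuple[CoxFit, list[str]]:
    """Assemble and fit the multivariable Cox model.

    Screen-selected covariates enter; within each declared collinear group
    only the designated representative is retained; forced covariates are
    added regardless of significance. Raises if the number of model
    covariates exceeds ``max_covariates`` (a categorical covariate counts
    once, however many indicator terms it expands to — the overfitting
    budget is per variable). Returns (fit, covariate names used).
    """
    by_name = {s.name: s for s in registry}
    if forced is None:
        forced = [s.name for s in registry if s.forced]
    chosen = [
        c for c in dict.fromkeys(screen.selected)  # preserve order, dedupe
        if not (c in by_name and by_name[c].screen_only)
    ]
    # collinear rule: if any member of a group was selected, keep only the
    # group's representative
    groups: dict[str, list[str]] = {}
    for s in registry:
        if s.collinear_group:
            groups.setdefault(s.collinear_group, []).append(s.name)
    for gname, members in groups.items():
        rep = next((m for m in members if by_name[m].representative), members[0])
        if any(m in chosen for m in members):
            chosen = [c for c in chosen if c not in members]
            chosen.append(rep)
    for f in forced:
        if f not in by_name:
            raise ValidationError(f"forced covariate {f!r} not in registry")
        if f not in chosen:
            chosen.append(f)
    if not chosen:
        raise ValidationError("no covariates selected and none forced")
    if len(chosen) > max_covariates:
        raise ValidationError(
            f"model has {len(chosen)} covariates, over the budget of "
            f"{max_covariates}: {chosen}"
        )

    specs = [by_name[c] for c in chosen]
    # complete cases across every model covariate
    cols = [s.column for s in specs]
    mask = df[cols].notna().all(axis=1)
    sub = df[mask]
    designs, terms = [], []
    for s in specs:
        d, t_names = _expand_design(sub, s)
        designs.append(d)
        terms.extend(t_names)
    design = pd.concat(designs, axis=1)
    # a level can vanish on the complete-case subset; drop its dead indicator
    keep = [c for c in design.columns if design[c].nunique() > 1]
    design = design[keep]
    fit = cox_fit(
        sub[time_col].to_numpy(dtype=float),
        sub[event_col].to_numpy(dtype=bool),
        design.to_numpy(dtype=float),
        names=list(design.columns),
        ties=ties,
    )
    return fit, chosen


# ---------------------------------------------------------------------------
# Group comparison (descriptive table with ANOVA / chi-square p-values)
# ---------------------------------------------------------------------------

def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table
    (no continuity correction). Returns (statistic, df, p)."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2x2")
    stat, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    return float(stat), int(dof), float(p)


def compare_groups(
    df: pd.DataFrame,
    group_col: str,
    numeric_vars: Sequence[str],
    categorical_vars: Sequence[str],
) -> pd.DataFrame:
    """Per-variable comparison across groups: one-way ANOVA F-test for
    numeric variables, Pearson chi-square for categorical ones (complete
    cases per variable). Variables that cannot be tested (constant, or a
    group entirely missing) are marked not-computable instead of raising."""
    groups = [g for g in df[group_col].dropna().unique()]
    if len(groups) < 2:
        raise ValidationError("compare_groups needs at least 2 groups")
    groups = sorted(groups, key=str)
    rows = []
    for var in numeric_vars:
        sub = df[[group_col, var]].dropna()
        samples = [sub.loc[sub[group_col] == g, var].to_numpy(dtype=float) for g in groups]
        row = {"variable": var, "kind": "numeric", "level": ""}
        for g, s in zip(groups, samples):
            row[f"{g}_n"] = len(s)
            row[f"{g}_summary"] = (
                f"mean {np.mean(s):.2f}, median {np.median(s):.2f}" if len(s) else "—"
            )
        if any(len(s) == 0 for s in samples) or sub[var].nunique() <= 1:
            row["p_value"] = np.nan
            row["note"] = "not computable"
        else:
            _, p = sps.f_oneway(*samples)
            row["p_value"] = float(p)
            row["note"] = ""
        rows.append(row)
    for var in categorical_vars:
        sub = df[[group_col, var]].dropna()
        tab = pd.crosstab(sub[var].astype(str), sub[group_col])
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            p = np.nan
            note = "not computable"
        else:
            _, _, p = chi_square_independence(tab.to_numpy())
            note = ""
        first = True
        for level in tab.index:
            row = {"variable": var, "kind": "categorical", "level": str(level)}
            for g in groups:
                cnt = int(tab.loc[level, g]) if g in tab.columns else 0
                tot = int(tab[g].sum()) if g in tab.columns else 0
                pct = 100.0 * cnt / tot if tot else 0.0
                row[f"{g}_n"] = cnt
                row[f"{g}_summary"] = f"{cnt} ({pct:.1f}%)"
            row["p_value"] = float(p) if first and not math.isnan(float(p)) else np.nan
            row["note"] = note if first else ""
            rows.append(row)
            first = False
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Power: minimum detectable hazard ratio (Schoenfeld events formula)
# ---------------------------------------------------------------------------

def min_detectable_hr(
    n_events: int,
    allocation: float = 0.5,
    alpha: float = 0.05,
    power: float = 0.80,
) -> float:
    """Smallest hazard ratio detectable with the given number of events.

    Schoenfeld's formula: ln(HR) = (z_{1-alpha/2} + z_power) /
    sqrt(d * a * (1 - a)) with d events and allocation fraction a.
    """
    if n_events < 1:
        raise ValidationError("n_events must be >= 1")
    if not (0.0 < allocation < 1.0):
        raise ValidationError("allocation must lie strictly in (0, 1)")
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise ValidationError("alpha and power must lie in (0, 1)")
    z_a = sps.norm.ppf(1.0 - alpha / 2.0)
    z_b = sps.norm.ppf(power)
    log_hr = (z_a + z_b) / math.sqrt(n_events * allocation * (1.0 - allocation))
    return math.exp(log_hr)
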