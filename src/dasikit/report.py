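"""End-to-end analysis pipeline and report generation.

``run_pipeline`` ties the stages together: cohort ingest (file or synthetic
config) -> derived indices -> DASI scoring -> descriptive and group-comparison
tables -> univariate Cox screen -> multivariable Cox model -> Kaplan-Meier
curves by readmission arm and by DASI band -> optional multiple-imputation
sensitivity analysis. The output is an :class:`AnalysisReport` of plain
DataFrames plus a provenance header; ``write_report`` serializes it as
delimited text and a markdown summary, byte-reproducibly for fixed inputs and
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, cohort_hash, collapse_rare_levels, group_admission_reason
from .errors import ConvergenceError, ValidationError
from .imputation import ImputationRun, sensitivity_analysis
from .indices import compute_indices
from .scoring import (
    DEFAULT_COMPLETENESS_FLOOR,
    FactorRegistry,
    default_registry,
    score_cohort,
)
from .survival import (
    CovariateSpec,
    CoxFit,
    ScreenResult,
    SurvivalCurve,
    build_multivariable,
    compare_groups,
    km_fit,
    logrank_test,
    univariate_screen,
)
from .synthetic import CohortConfig, generate

_NUMERIC_COMPARE = [
    "age", "healthcare_visits_6mo", "weight_kg", "corrected_calcium", "creatinine",
    "hemoglobin", "length_of_index_admission", "lymphocytes", "nlr", "neutrophils",
    "plr", "platelets", "sii", "albumin", "sodium", "wbc", "n_medications", "pni",
    "dasi_score",
]
_CATEGORICAL_COMPARE = [
    "sex", "marital_status", "language", "race", "fall_risk", "admission_reason",
    "cancer_type", "dasi_category", "metastasis",
]


def default_covariate_registry() -> list[CovariateSpec]:
    """The packaged covariate registry for the screen and model building."""
    with resources.files("dasikit.data").joinpath("covariates.yaml").open(
        encoding="utf-8"
    ) as fh:
        spec = yaml.safe_load(fh)
    return [CovariateSpec(**item) for item in spec["covariates"]]


def load_covariate_registry(path: str | Path) -> list[CovariateSpec]:
    with open(path, encoding="utf-8") as fh:
        spec = yaml.safe_load(fh)
    return [CovariateSpec(**item) for item in spec["covariates"]]


def analysis_frame(
    cohort: Cohort,
    registry: Optional[FactorRegistry] = None,
    denominator_policy: str = "fixed_23",
    completeness_floor: int = DEFAULT_COMPLETENESS_FLOOR,
    pni_convention: str = "product",
    rare_level_min_count: int = 10,
) -> pd.DataFrame:
    """One analysis row per patient: raw fields, derived indices, grouped
    admission reason, pooled cancer type, DASI score and band."""
    df = cohort.to_dataframe()
    idx_rows = []
    for rec in cohort:
        d = compute_indices(rec.labs, rec.weight_kg, rec.height_cm,
                            pni_convention=pni_convention)
        idx_rows.append({"nlr": d.nlr, "plr": d.plr, "sii": d.sii,
                         "pni": d.pni, "bmi": d.bmi})
    df = pd.concat([df, pd.DataFrame(idx_rows, index=df.index)], axis=1)
    df["admission_reason"] = [
        group_admission_reason(c) if isinstance(c, str) and c.strip() else None
        for c in df["chief_complaint"]
    ]
    raw = df["cancer_type_raw"]
    known = raw.notna()
    if known.any():
        collapsed = collapse_rare_levels(
            [str(v).strip().casefold() for v in raw[known]], min_count=rare_level_min_count
        )
        df["cancer_type"] = None
        df.loc[known, "cancer_type"] = collapsed
    else:
        df["cancer_type"] = None
    scored = score_cohort(
        cohort, registry=registry, denominator_policy=denominator_policy,
        completeness_floor=completeness_floor,
    )
    df["dasi_n_evaluable"] = scored["n_evaluable"].to_numpy()
    df["dasi_score"] = scored["dasi_score"].to_numpy()
    df["dasi_category"] = scored["dasi_category"].to_numpy()
    return df


def cohort_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table: n / mean / median / sd / min / max / missing for
    numeric variables, level counts and percentages for categorical ones."""
    rows = []
    n_total = len(df)
    for var in _NUMERIC_COMPARE + ["survival_time"]:
        s = pd.to_numeric(df[var], errors="coerce")
        obs = s.dropna()
        rows.append({
            "variable": var, "level": "", "n": int(obs.size),
            "mean": round(float(obs.mean()), 4) if obs.size else np.nan,
            "median": round(float(obs.median()), 4) if obs.size else np.nan,
            "sd": round(float(obs.std()), 4) if obs.size > 1 else np.nan,
            "min": float(obs.min()) if obs.size else np.nan,
            "max": float(obs.max()) if obs.size else np.nan,
            "missing": int(n_total - obs.size), "percent": np.nan,
        })
    for var in ["readmitted_30d", "event"] + _CATEGORICAL_COMPARE:
        s = df[var]
        obs = s.dropna()
        counts = obs.astype(str).value_counts().sort_index()
        for level, cnt in counts.items():
            rows.append({
                "variable": var, "level": level, "n": int(cnt),
                "mean": np.nan, "median": np.nan, "sd": np.nan,
                "min": np.nan, "max": np.nan,
                "missing": int(n_total - obs.size),
                "percent": round(100.0 * cnt / obs.size, 2),
            })
    return pd.DataFrame(rows)


def _fmt_days(x: Optional[float]) -> str:
    return "undetermined" if x is None else f"{x:g}"


@dataclass
class KmBlock:
    """KM strata for one grouping: per-stratum curves plus the log-rank test."""

    grouping: str
    curves: Mapping[str, SurvivalCurve]
    logrank_statistic: float
    logrank_df: int
    logrank_p: float

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, c in self.curves.items():
            rows.append({
                "stratum": name, "n": c.n, "events": c.n_events,
                "median_days": _fmt_days(c.median),
                "median_ci_low": _fmt_days(c.median_ci[0]),
                "median_ci_high": _fmt_days(c.median_ci[1]),
                "logrank_p": self.logrank_p,
            })
        return pd.DataFrame(rows)

    def coordinates(self) -> pd.DataFrame:
        frames = []
        for name, c in self.curves.items():
            frames.append(pd.DataFrame({
                "stratum": name, "time": c.times, "survival": c.survival,
                "variance": c.variance, "at_risk": c.at_risk, "events": c.events,
            }))
        return pd.concat(frames, ignore_index=True)


def km_by(df: pd.DataFrame, group_col: str, order: Optional[Sequence] = None) -> KmBlock:
    sub = df[df[group_col].notna()]
    levels = list(order) if order else sorted(sub[group_col].unique(), key=str)
    samples, curves = [], {}
    for lev in levels:
        g = sub[sub[group_col] == lev]
        if g.empty:
            continue
        t = g["survival_time"].to_numpy(dtype=float)
        e = g["event"].to_numpy(dtype=bool)
        curves[str(lev)] = km_fit(t, e)
        samples.append((t, e))
    if len(samples) < 2:
        raise ValidationError(f"grouping {group_col!r} has fewer than 2 non-empty strata")
    lr = logrank_test(samples)
    return KmBlock(grouping=group_col, curves=curves,
                   logrank_statistic=lr.statistic, logrank_df=lr.df, logrank_p=lr.p_value)


@dataclass
class AnalysisReport:
    provenance: dict
    cohort_summary: pd.DataFrame
    group_comparison: pd.DataFrame
    screen: ScreenResult
    multivariable: Optional[CoxFit]
    multivariable_covariates: list[str]
    km_readmission: KmBlock
    km_dasi: Optional[KmBlock]
    dasi_table: pd.DataFrame
    imputation: Optional[ImputationRun] = None
    notes: list[str] = field(default_factory=list)


def _trim_to_budget(screen: ScreenResult, registry: Sequence[CovariateSpec],
                    forced: list[str], budget: int) -> tuple[list[str], list[str]]:
    """Keep the most significant screen selections within the covariate
    budget (forced covariates always stay). Returns (kept, dropped)."""
    by_name = {s.name: s for s in registry}
    tbl = screen.table
    sel = [s for s in screen.selected
           if s not in forced and not by_name[s].screen_only]
    pmin = {}
    for name in sel:
        sub = tbl[tbl["covariate"] == name]["p_value"].dropna()
        pmin[name] = float(sub.min()) if len(sub) else 1.0
    # collapse collinear groups before counting
    groups: dict[str, list[str]] = {}
    for s in registry:
        if s.collinear_group:
            groups.setdefault(s.collinear_group, []).append(s.name)
    for members in groups.values():
        present = [m for m in members if m in sel]
        if present:
            rep = next((m for m in members if by_name[m].representative), members[0])
            best_p = min(pmin[m] for m in present)
            sel = [s for s in sel if s not in members]
            pmin[rep] = best_p
            sel.append(rep)
    sel.sort(key=lambda s: (pmin[s], s))
    room = budget - len(forced)
    kept, dropped = sel[:max(room, 0)], sel[max(room, 0):]
    return kept, dropped


def run_pipeline(
    cohort: Optional[Cohort] = None,
    config: Optional[CohortConfig] = None,
    factor_registry: Optional[FactorRegistry] = None,
    covariate_registry: Optional[Sequence[CovariateSpec]] = None,
    denominator_policy: str = "fixed_23",
    completeness_floor: int = DEFAULT_COMPLETENESS_FLOOR,
    ties: str = "efron",
    max_covariates: int = 13,
    trim_to_budget: bool = True,
    do_impute: bool = True,
    impute_m: int = 20,
    seed: int = 0,
) -> AnalysisReport:
    """Execute the full analysis; exactly one of ``cohort`` / ``config``.

    With ``trim_to_budget`` (default), screen selections beyond the covariate
    budget are dropped least-significant-first and recorded in the report
    notes; with it off, an over-budget model raises instead.
    """
    if (cohort is None) == (config is None):
        raise ValidationError("provide exactly one of cohort or config")
    if config is not None:
        config = CohortConfig.from_dict({**config.to_dict(), "seed": int(seed)})
        cohort = generate(config)
    if factor_registry is None:
        factor_registry = default_registry()
    if covariate_registry is None:
        covariate_registry = default_covariate_registry()
    notes: list[str] = [
        f"denominator_policy={denominator_policy}",
        f"completeness_floor={completeness_floor}",
        f"ties={ties}",
        f"factor_registry_checksum={factor_registry.checksum}",
    ]

    df = analysis_frame(
        cohort, registry=factor_registry,
        denominator_policy=denominator_policy, completeness_floor=completeness_floor,
    )
    summary = cohort_summary(df)
    comparison = compare_groups(
        df.assign(readmitted_30d=df["readmitted_30d"].map({True: "readmitted", False: "control"})),
        "readmitted_30d", _NUMERIC_COMPARE, _CATEGORICAL_COMPARE,
    )
    screen = univariate_screen(df, covariate_registry, ties=ties)

    forced = [s.name for s in covariate_registry if s.forced]
    screen_for_model = screen
    if trim_to_budget:
        kept, dropped = _trim_to_budget(screen, covariate_registry, forced, max_covariates)
        if dropped:
            notes.append(f"screen selections beyond the {max_covariates}-covariate "
                         f"budget dropped (largest p first): {dropped}")
        screen_for_model = ScreenResult(
            table=screen.table, selected=kept, degenerate=screen.degenerate,
            alpha=screen.alpha,
        )
    multivariable, chosen = None, []
    try:
        multivariable, chosen = build_multivariable(
            df, screen_for_model, covariate_registry, forced=forced,
            max_covariates=max_covariates, ties=ties,
        )
    except (ValidationError, ConvergenceError) as exc:
        notes.append(f"multivariable model not fitted: {exc}")

    km_readm = km_by(
        df.assign(readmitted_30d=df["readmitted_30d"].map({True: "readmitted", False: "control"})),
        "readmitted_30d", order=["control", "readmitted"],
    )
    km_dasi = None
    try:
        km_dasi = km_by(df, "dasi_category", order=["low", "moderate", "high"])
    except ValidationError as exc:
        notes.append(f"DASI-stratified KM unavailable: {exc}")

    dasi_table = score_cohort(
        cohort, registry=factor_registry,
        denominator_policy=denominator_policy, completeness_floor=completeness_floor,
    )

    imput = None
    if do_impute and multivariable is not None:
        by_name = {s.name: s for s in covariate_registry}
        specs = [by_name[c] for c in chosen]
        focal = "readmission" if "readmission" in chosen else chosen[0]
        imput_seed = int(seed) % (2**31 - 1)
        imput = sensitivity_analysis(
            df, specs, focal=focal, m=impute_m, seed=imput_seed, ties=ties,
        )

    provenance = {
        "package_version": __version__,
        "seed": int(seed),
        "cohort_hash": cohort_hash(cohort),
        "cohort_provenance": cohort.provenance,
        "n_patients": len(cohort),
        "factor_registry_checksum": factor_registry.checksum,
    }
    return AnalysisReport(
        provenance=provenance, cohort_summary=summary, group_comparison=comparison,
        screen=screen, multivariable=multivariable, multivariable_covariates=chosen,
        km_readmission=km_readm, km_dasi=km_dasi, dasi_table=dasi_table,
        imputation=imput, notes=notes,
    )


_FLOAT_FMT = "%.10g"


def write_report(report: AnalysisReport, out_dir: str | Path) -> list[Path]:
    """Serialize every report table as TSV plus a markdown summary.

    Output is byte-identical across repeated runs with identical inputs and
    seed (tables are written with a fixed float format).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
        written.append(p)

    emit(report.cohort_summary, "cohort_summary.tsv")
    emit(report.group_comparison, "group_comparison.tsv")
    emit(report.screen.table, "univariate_screen.tsv")
    if report.multivariable is not None:
        emit(report.multivariable.summary().reset_index(names="term"), "multivariable.tsv")
    emit(report.km_readmission.summary(), "km_readmission_summary.tsv")
    emit(report.km_readmission.coordinates(), "km_readmission_curves.tsv")
    if report.km_dasi is not None:
        emit(report.km_dasi.summary(), "km_dasi_summary.tsv")
        emit(report.km_dasi.coordinates(), "km_dasi_curves.tsv")
    emit(report.dasi_table, "dasi_scores.tsv")
    if report.imputation is not None:
        emit(report.imputation.summary(), "imputation_sensitivity.tsv")

    lines = ["# Analysis report", ""]
    lines.append("## Provenance")
    for k, v in report.provenance.items():
        lines.append(f"- {k}: {v}")
    lines.append("")
    lines.append("## Settings and notes")
    for note in report.notes:
        lines.append(f"- {note}")
    lines.append("")
    lines.append("## Kaplan-Meier medians (days)")
    for block in filter(None, [report.km_readmission, report.km_dasi]):
        lines.append(f"### by {block.grouping} "
                     f"(log-rank chi2={block.logrank_statistic:.4g}, "
                     f"df={block.logrank_df}, p={block.logrank_p:.3g})")
        for name, c in block.curves.items():
            lines.append(
                f"- {name}: n={c.n}, events={c.n_events}, median={_fmt_days(c.median)} "
                f"(95% CI {_fmt_days(c.median_ci[0])} to {_fmt_days(c.median_ci[1])})"
            )
        lines.append("")
    if report.multivariable is not None:
        lines.append("## Multivariable Cox model")
        lines.append(f"- covariates: {', '.join(report.multivariable_covariates)}")
        s = report.multivariable.summary()
        for term, row in s.iterrows():
            lines.append(
                f"- {term}: HR {row['hazard_ratio']:.3g} "
                f"(95% CI {row['ci_lower']:.3g}-{row['ci_upper']:.3g}), p={row['p_value']:.3g}"
            )
        lines.append("")
    if report.imputation is not None:
        lo, hi = report.imputation.hr_range
        plo, phi = report.imputation.pooled_ci
        lines.append("## Imputation sensitivity")
        lines.append(
            f"- focal term {report.imputation.focal_term}: HR range: {lo:.2f}-{hi:.2f} "
            f"across {report.imputation.m} imputed datasets"
        )
        lines.append(
            f"- Rubin-pooled HR {report.imputation.pooled_hr:.3g} "
            f"(95% CI {plo:.3g}-{phi:.3g})"
        )
        lines.append("")
    p = out / "summary.md"
    p.write_text("\n".join(lines), encoding="utf-8")
    written.append(p)
    return written
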