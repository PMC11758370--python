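"""Cohort construction and the full registry-style analysis pipeline.

Reproduces the study workflow on any table with the registry-like schema:
exclusion of emergency surgery and unknown survival status, administrative
truncation at the follow-up horizon, categorization of age / ASA / period,
a demography-and-fatality descriptive table, join-point subgroup fits
gated on an overall heterogeneity test, and the stage-IV sensitivity
re-fit. Complete-case handling is per analysis: rows missing a variable a
given analysis uses are dropped from that analysis only, and the
missingness is logged in the returned objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .estimation import (
    Cohort,
    ComparisonResult,
    FitConfig,
    FitResult,
    NoEventsError,
    fit_with_ci,
    overall_test,
    parameter_equality_test,
)
from .model import REPORT_SCALE

__all__ = [
    "SCHEMA_COLUMNS",
    "ExclusionReport",
    "read_cohort_csv",
    "write_cohort_csv",
    "apply_exclusions",
    "modeling_subset",
    "categorize",
    "descriptive_table",
    "headline_fatality",
    "SubgroupAnalysis",
    "subgroup_fit",
    "sensitivity_exclude_stage_iv",
]

SCHEMA_COLUMNS = [
    "id", "age", "sex", "asa", "year", "site", "stage", "urgency",
    "survival_time", "vital_status", "status_known",
]

_ENUMS = {
    "sex": {"male", "female"},
    "asa": {"I", "II", "III", "IV"},
    "site": {"colon", "rectal"},
    "stage": {"I", "II", "III", "IV", "complete_response"},
    "urgency": {"elective", "emergency"},
    "vital_status": {"dead", "alive"},
}


def read_cohort_csv(path) -> pd.DataFrame:
    """Read the cohort CSV dialect (empty field = missing, integer days)."""
    table = pd.read_csv(
        path,
        dtype={
            "id": "Int64", "age": "Int64", "year": "Int64",
            "survival_time": "Int64", "status_known": "Int64",
        },
        keep_default_na=True,
    )
    missing = [c for c in SCHEMA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")
    return table


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, na_rep="")


def validate_table(table: pd.DataFrame, drop_invalid: bool = False) -> pd.DataFrame:
    """Check enumerations and day ranges row-wise.

    Collects offending rows; raises with a per-column report unless
    ``drop_invalid`` is set, in which case the offending rows are removed.
    """
    bad = pd.Series(False, index=table.index)
    problems = []
    for col, allowed in _ENUMS.items():
        vals = table[col]
        invalid = vals.notna() & ~vals.isin(list(allowed))
        if invalid.any():
            problems.append(f"{col}: {sorted(set(vals[invalid].astype(str)))}")
            bad |= invalid
    neg = table["survival_time"].notna() & (table["survival_time"] < 0)
    if neg.any():
        problems.append("survival_time: negative values")
        bad |= neg
    if problems and not drop_invalid:
        raise ValueError("invalid values in cohort table — " + "; ".join(problems))
    return table[~bad].copy() if problems else table


@dataclass(frozen=True)
class ExclusionReport:
    """Row counts along the exclusion chain (non-increasing)."""

    steps: tuple  # of (label, count)

    @property
    def counts(self) -> tuple:
        return tuple(c for _, c in self.steps)

    def to_dict(self) -> dict:
        return {label: count for label, count in self.steps}


def apply_exclusions(
    raw_table: pd.DataFrame,
    horizon: float = 180.0,
    drop_invalid: bool = False,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Build the analyzable elective cohort.

    Keeps elective surgery with known survival status, then truncates
    follow-up at the administrative horizon: survivors past ``horizon``
    are censored there (vital status alive). Returns the filtered table
    and the count chain.
    """
    table = validate_table(raw_table, drop_invalid=drop_invalid)
    steps = [("total", len(table))]
    table = table[table["urgency"] == "elective"]
    steps.append(("elective", len(table)))
    known = table["status_known"].fillna(0).astype(int) == 1
    table = table[known & table["survival_time"].notna()].copy()
    steps.append(("status_known", len(table)))
    over = table["survival_time"] > horizon
    table.loc[over, "survival_time"] = int(horizon)
    table.loc[over, "vital_status"] = "alive"
    steps.append(("analyzable", len(table)))
    return table.reset_index(drop=True), ExclusionReport(tuple(steps))


def modeling_subset(
    analysis_table: pd.DataFrame, origin: float = 3.0
) -> tuple[Cohort, int]:
    """Drop deaths before the acute-phase origin and return the fit cohort.

    Mirrors the exclusion of the first two postoperative days from
    modelling: subjects who died on days 0–2 leave the risk set before the
    model starts. Returns the estimation cohort and the number dropped.
    """
    if origin <= 0:
        raise ValueError("origin must be positive")
    dead = analysis_table["vital_status"] == "dead"
    early = dead & (analysis_table["survival_time"] < origin)
    kept = analysis_table[~early]
    time = kept["survival_time"].to_numpy(float)
    # censored subjects with follow-up shorter than the origin carry no
    # information for the model and would violate the likelihood domain
    valid = time >= origin
    cohort = Cohort(time[valid], (kept["vital_status"] == "dead").to_numpy()[valid])
    return cohort, int(early.sum())


_AGE_BINS = [(0, 69, "0-69"), (70, 79, "70-79"), (80, np.inf, "80+")]
_PERIODS = [(2007, 2011, "2007-2011"), (2012, 2016, "2012-2016"), (2017, 2020, "2017-2020")]
_ASA_GROUPS = {"I": "I", "II": "II", "III": "III-IV", "IV": "III-IV"}


def categorize(table: pd.DataFrame) -> pd.DataFrame:
    """Add the derived grouping columns age_group, asa_group and period.

    Boundaries are inclusive as conventionally printed (age 69 is 0–69,
    70 is 70–79, 80 and over is 80+; year 2011 closes the first period;
    ASA IV merges into III–IV). Missing inputs stay missing; years outside
    2007–2020 become the explicit label "unknown".
    """
    out = table.copy()

    def age_group(a):
        if pd.isna(a):
            return pd.NA
        for lo, hi, label in _AGE_BINS:
            if lo <= a <= hi:
                return label
        return pd.NA

    def period(y):
        if pd.isna(y):
            return pd.NA
        for lo, hi, label in _PERIODS:
            if lo <= y <= hi:
                return label
        return "unknown"

    out["age_group"] = out["age"].map(age_group).astype("string")
    out["period"] = out["year"].map(period).astype("string")
    out["asa_group"] = out["asa"].map(lambda v: _ASA_GROUPS.get(v, pd.NA)).astype("string")
    return out


def _fatality_flags(table: pd.DataFrame) -> dict[str, pd.Series]:
    dead = table["vital_status"] == "dead"
    t = table["survival_time"]
    return {
        "dead_0_30": dead & (t <= 30),
        "dead_0_90": dead & (t <= 90),
        "dead_0_2": dead & (t <= 2),
        "dead_3_180": dead & (t >= 3) & (t <= 180),
        "censored": ~dead,
    }


def descriptive_table(table: pd.DataFrame) -> pd.DataFrame:
    """Demography-and-fatality summary in the published table's shape.

    One row per category level with per-site and total "n" and "pct"
    columns; percentages use complete-case denominators (rows with the
    category observed) and are rounded to 1 decimal. A separate "missing"
    block reports how many rows lacked each variable.
    """
    cat = categorize(table)
    sites = ["colon", "rectal"]
    blocks = []

    def add_row(factor, level, masks_by_scope, denominators):
        row = {"factor": factor, "level": level}
        for scope in sites + ["total"]:
            n = int(masks_by_scope[scope].sum())
            denom = denominators[scope]
            row[f"{scope}_n"] = n
            row[f"{scope}_pct"] = round(100.0 * n / denom, 1) if denom else 0.0
        blocks.append(row)

    site_mask = {s: cat["site"] == s for s in sites}
    site_mask["total"] = pd.Series(True, index=cat.index)

    for factor in ["sex", "asa_group", "age_group", "period", "stage"]:
        observed = cat[factor].notna() & (cat[factor] != "unknown")
        denominators = {s: int((observed & site_mask[s]).sum()) for s in site_mask}
        for level in cat.loc[observed, factor].dropna().unique():
            masks = {s: (cat[factor] == level) & site_mask[s] & observed for s in site_mask}
            add_row(factor, str(level), masks, denominators)
        n_missing = {s: int((~observed & site_mask[s]).sum()) for s in site_mask}
        if any(n_missing.values()):
            add_row(factor, "missing", {s: ~observed & site_mask[s] for s in site_mask},
                    {s: int(site_mask[s].sum()) for s in site_mask})

    denominators = {s: int(site_mask[s].sum()) for s in site_mask}
    for label, flag in _fatality_flags(cat).items():
        masks = {s: flag & site_mask[s] for s in site_mask}
        add_row("fatality", label, masks, denominators)
    return pd.DataFrame(blocks)


def headline_fatality(table: pd.DataFrame, origin: float = 3.0, horizon: float = 180.0) -> dict:
    """Headline percentages at 2-decimal precision, both windowing
    conventions for the modelled interval: deaths recorded on days
    ``origin``–``horizon`` and all deaths up to ``horizon`` (which folds
    the pre-origin deaths in)."""
    dead = table["vital_status"] == "dead"
    t = table["survival_time"]
    n = len(table)

    def pct(k):
        return round(100.0 * k / n, 2)

    out = {
        "n": n,
        "dead_0_30": int((dead & (t <= 30)).sum()),
        "dead_0_90": int((dead & (t <= 90)).sum()),
        "dead_0_2": int((dead & (t < origin)).sum()),
        "dead_3_180": int((dead & (t >= origin) & (t <= horizon)).sum()),
        "dead_0_180": int((dead & (t <= horizon)).sum()),
    }
    for key in list(out):
        if key != "n":
            out[f"{key}_pct"] = pct(out[key])
    return out


@dataclass(frozen=True)
class SubgroupAnalysis:
    """Stratified join-point analysis: gate test, per-parameter tests,
    per-level fits and the formatted report table."""

    overall: Optional[ComparisonResult]
    parameter_tests: Mapping[str, ComparisonResult]
    fits: Mapping[str, FitResult]
    table: pd.DataFrame
    gated: bool
    missing_rows: int


def _format_fit_row(level: str, fit: FitResult) -> dict:
    def rate_cell(name):
        v = getattr(fit.params, name) * REPORT_SCALE
        ci = fit.ci.get(name)
        if ci is None:
            return f"{v:.2f}"
        return f"{v:.2f} ({ci.lower * REPORT_SCALE:.2f}-{ci.upper * REPORT_SCALE:.2f})"

    tau = fit.params.phase_shift
    ci = fit.ci.get("phase_shift")
    tau_cell = f"{tau:.1f}" if ci is None else f"{tau:.1f} ({ci.lower:.1f}-{ci.upper:.1f})"
    return {
        "level": level,
        "n": fit.n_subjects,
        "events": fit.n_events,
        "acute_rate_per_1000": rate_cell("acute_rate"),
        "background_rate_per_1000": rate_cell("background_rate"),
        "phase_shift_days": tau_cell,
    }


def subgroup_fit(
    analysis_table: pd.DataFrame,
    stratify_by: str,
    within: Optional[Mapping[str, str]] = None,
    config: FitConfig = FitConfig(),
    coverage: float = 0.95,
    force: bool = False,
) -> SubgroupAnalysis:
    """Stratified fits with likelihood-ratio gating.

    Splits the (categorized) table by ``stratify_by`` — optionally after
    filtering with ``within`` (e.g. age groups within ASA II) — runs the
    overall heterogeneity test, and only when it rejects at 5% (or
    ``force`` is set) proceeds to per-parameter equality tests and
    per-level fits with profile CIs. A stratum without events raises,
    naming the stratum, so the caller can merge sparse levels.
    """
    cat = categorize(analysis_table)
    if within:
        for col, value in within.items():
            cat = cat[cat[col] == value]
    observed = cat[stratify_by].notna() & (cat[stratify_by] != "unknown")
    missing_rows = int((~observed).sum())
    cat = cat[observed]
    levels = sorted(cat[stratify_by].dropna().unique())
    if not levels:
        raise ValueError(f"no observed levels of {stratify_by!r}")

    cohorts = {}
    for level in levels:
        cohort, _ = modeling_subset(cat[cat[stratify_by] == level], config.origin)
        if cohort.n_events == 0:
            raise NoEventsError(
                f"stratum {stratify_by}={level!r} has no deaths on/after day "
                f"{config.origin}; merge it before fitting"
            )
        cohorts[str(level)] = cohort

    if len(cohorts) == 1:
        fit = fit_with_ci(next(iter(cohorts.values())), config, coverage)
        table = pd.DataFrame([_format_fit_row(levels[0], fit)])
        return SubgroupAnalysis(None, {}, {str(levels[0]): fit}, table, False, missing_rows)

    gate = overall_test(cohorts, config)
    gated = gate.p_value >= 0.05 and not force
    parameter_tests: dict[str, ComparisonResult] = {}
    fits: dict[str, FitResult] = {}
    rows = []
    if not gated:
        for name in ("acute_rate", "background_rate", "phase_shift"):
            parameter_tests[name] = parameter_equality_test(cohorts, name, config)
        for level, cohort in cohorts.items():
            fit = fit_with_ci(cohort, config, coverage)
            fits[level] = fit
            rows.append(_format_fit_row(level, fit))
    table = pd.DataFrame(rows)
    return SubgroupAnalysis(gate, parameter_tests, fits, table, gated, missing_rows)


def sensitivity_exclude_stage_iv(
    analysis_table: pd.DataFrame,
    config: FitConfig = FitConfig(),
    coverage: float = 0.95,
) -> tuple[FitResult, int]:
    """Repeat the main fit without metastatic (stage IV) disease.

    Complete-case on stage: rows with missing stage are dropped for this
    analysis. Returns the re-fit and the number of stage-IV exclusions.
    """
    if "stage" not in analysis_table.columns:
        raise ValueError("stage column is required for the sensitivity analysis")
    staged = analysis_table[analysis_table["stage"].notna()]
    kept = staged[staged["stage"] != "IV"]
    excluded = int((staged["stage"] == "IV").sum())
    cohort, _ = modeling_subset(kept, config.origin)
    return fit_with_ci(cohort, config, coverage), excluded
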