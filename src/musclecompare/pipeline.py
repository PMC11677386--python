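"""Cohort I/O, stratified reporting and cohort-level analyses.

Ties the stages together: validated CSV round-trips, per-stratum biomarker
summaries with normality-gated location tests, pairwise-complete correlation
matrices, quantitative agreement reports (Pearson + CCC + Bland–Altman +
paired location test) and categorical prevalence/kappa grids.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import ValidationError
from scipy import stats

from . import agreement, biomarkers, diagnostics
from .errors import CohortValidationError, DomainError
from .records import SubjectRecord

__all__ = [
    "read_cohort",
    "write_cohort",
    "stratified_summary",
    "correlation_matrix",
    "agreement_report",
    "kappa_grid",
    "diagnose_cohort",
    "prevalence_table",
]

log = logging.getLogger("musclecompare")

_BOOL_FIELDS = {"weight_loss_voluntary"}


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    """Read and validate a cohort CSV (one row per subject, schema headers).

    Empty cells are missing values.  Row failures are collected and raised
    together as :class:`CohortValidationError` with 1-based data-row numbers;
    magnitude checks add unit hints (e.g. a height of 164 suggests cm).
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if frame.empty:
        warnings.warn(f"{path}: empty cohort file", stacklevel=2)
        return []
    unknown = set(frame.columns) - set(SubjectRecord.model_fields)
    if unknown:
        raise CohortValidationError(
            [(0, f"unknown column(s): {', '.join(sorted(unknown))}")]
        )
    records, row_errors = [], []
    for i, row in enumerate(frame.to_dict("records"), start=1):
        fields = {}
        for key, value in row.items():
            if value is None or (isinstance(value, float) and np.isnan(value)):
                continue
            fields[key] = bool(value) if key in _BOOL_FIELDS else value
        try:
            records.append(SubjectRecord(**fields))
        except ValidationError as exc:
            for err in exc.errors():
                loc = ".".join(str(p) for p in err["loc"]) or "record"
                row_errors.append((i, f"{loc}: {err['msg']}"))
    if row_errors:
        raise CohortValidationError(row_errors)
    log.info("read %d records from %s", len(records), path)
    return records


def write_cohort(records: Sequence[SubjectRecord], path: str | Path) -> None:
    frame = pd.DataFrame([r.model_dump() for r in records])
    frame.to_csv(path, index=False)
    log.info("wrote %d records to %s", len(frame), path)


# ---------------------------------------------------------------------------
# Stratified summaries

def _stratum_labels(frame: pd.DataFrame, stratifier: str, age_threshold: float):
    if stratifier == "sex":
        return frame["sex"].map({0: "female", 1: "male"})
    if stratifier == "age":
        return np.where(frame["age"] >= age_threshold,
                        f"age>={age_threshold:g}", f"age<{age_threshold:g}")
    if stratifier == "obesity":
        return np.where(frame["bmi"] >= 30.0, "obese", "non-obese")
    if stratifier == "glim":
        return np.where(frame["glim"] > 0, "malnourished", "well-nourished")
    raise DomainError(f"unknown stratifier {stratifier!r}")


def stratified_summary(
    frame: pd.DataFrame,
    variables: Sequence[str],
    stratifier: str,
    age_threshold: float = 70.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-stratum summary of biomarkers with a gated two-group location test.

    One row per (stratum, variable): n, mean, sd, median, iqr, min, max; for
    two-level stratifiers the location-test name and p-value are attached to
    each variable.  Strata with fewer than 3 non-missing values have their
    statistics suppressed (NaN) and are marked in the ``note`` column.
    """
    labels = pd.Series(_stratum_labels(frame, stratifier, age_threshold),
                       index=frame.index)
    level_names = sorted(pd.unique(labels.dropna()))
    rows = []
    for var in variables:
        groups = {
            lev: frame.loc[labels == lev, var].dropna().to_numpy()
            for lev in level_names
        }
        test_name, p = None, None
        if len(level_names) == 2 and all(g.size >= 3 for g in groups.values()):
            a, b = (groups[lev] for lev in level_names)
            res = agreement.compare_location(a, b, paired=False, alpha=alpha)
            test_name, p = res.test, res.p_value
        for lev in level_names:
            g = groups[lev]
            if g.size < 3:
                rows.append({
                    "variable": var, "stratum": lev, "n": g.size,
                    "note": "suppressed (n < 3)",
                })
                continue
            q1, med, q3 = np.percentile(g, [25, 50, 75])
            rows.append({
                "variable": var, "stratum": lev, "n": g.size,
                "mean": g.mean(), "sd": g.std(ddof=1),
                "median": med, "iqr": q3 - q1,
                "min": g.min(), "max": g.max(),
                "test": test_name, "p": p, "note": "",
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Correlation matrices

def correlation_matrix(
    frame: pd.DataFrame, variables: Sequence[str], method: str = "pearson",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete correlation matrix with per-cell p-values.

    Cells with fewer than 3 complete pairs are NaN.  ``method`` is "pearson"
    or "spearman".
    """
    if method not in ("pearson", "spearman"):
        raise DomainError(f"unknown correlation method {method!r}")
    func = stats.pearsonr if method == "pearson" else stats.spearmanr
    k = len(variables)
    corr = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    pvals = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    for i, a in enumerate(variables):
        for j, b in enumerate(variables):
            if j <= i:
                continue
            pair = frame[[a, b]].dropna()
            if len(pair) < 3 or pair[a].nunique() < 2 or pair[b].nunique() < 2:
                r = p = np.nan
            else:
                res = func(pair[a], pair[b])
                r, p = float(res.statistic), float(res.pvalue)
            corr.iloc[i, j] = corr.iloc[j, i] = r
            pvals.iloc[i, j] = pvals.iloc[j, i] = p
    return corr, pvals


# ---------------------------------------------------------------------------
# Agreement reports

def agreement_report(
    frame: pd.DataFrame, pairs: Sequence[tuple[str, str]], alpha: float = 0.05,
) -> list[dict]:
    """Quantitative agreement for (reference, index) column pairs.

    Per pair: Pearson r, Lin's CCC with CI and category, Bland–Altman fields,
    and the paired normality-gated location test — on pairwise-complete rows.
    """
    reports = []
    for ref_col, idx_col in pairs:
        for col in (ref_col, idx_col):
            if col not in frame.columns:
                raise DomainError(f"unknown column {col!r}")
        # build positionally so a self-pair (ref == idx) stays well-formed
        pair = pd.DataFrame(
            {"ref": frame[ref_col], "idx": frame[idx_col]}
        ).dropna()
        ref = pair["ref"].to_numpy(float)
        idx = pair["idx"].to_numpy(float)
        ba = agreement.bland_altman(ref, idx)
        ccc = agreement.lin_ccc(ref, idx)
        loc = agreement.compare_location(ref, idx, paired=True, alpha=alpha)
        try:
            r = agreement.pearson_r(ref, idx)
        except DomainError:
            r = float("nan")
        reports.append({
            "reference": ref_col,
            "index": idx_col,
            "n": len(pair),
            "pearson_r": r,
            "ccc": dataclasses.asdict(ccc),
            "bland_altman": dataclasses.asdict(ba),
            "location_test": dataclasses.asdict(loc),
        })
    return reports


def kappa_grid(
    flags: pd.DataFrame, pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Cohen's kappa for every requested (or all) pair of flag columns."""
    cols = list(flags.columns)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]]
    rows = []
    for a, b in pairs:
        try:
            res = agreement.cohen_kappa(flags[a].astype(int), flags[b].astype(int))
            rows.append({"a": a, "b": b, "kappa": res.kappa,
                         "p_value": res.p_value, "n": res.n})
        except DomainError as exc:
            rows.append({"a": a, "b": b, "kappa": np.nan,
                         "p_value": np.nan, "n": len(flags), "note": str(exc)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort-level diagnosis

def diagnose_cohort(
    records: Sequence[SubjectRecord],
    cutoff_sets: Optional[Mapping[str, diagnostics.CutoffSet]] = None,
    grip_table: Optional[diagnostics.GripNormativeTable] = None,
) -> pd.DataFrame:
    """Apply every diagnostic rule to a cohort.

    Returns one row per subject: BMI category, obesity, GLIM severity,
    dynapenia, an ``atrophy_<set>`` flag per cut-off set (myosteatosis for
    radiodensity-based sets) and a ``sarcopenia_<set>`` flag per atrophy
    definition.  A flag is NA when its biomarker is missing; an atrophy flag
    never silently defaults when covariates are out of range.
    """
    cutoff_sets = dict(cutoff_sets if cutoff_sets is not None
                       else diagnostics.shipped_cutoff_sets())
    if grip_table is None:
        grip_table = diagnostics.load_grip_table("synthetic_grip_p10")
    rows = []
    for rec in records:
        derived = biomarkers.derive_all(rec)
        bmi = derived.bmi
        category, obese = diagnostics.bmi_category(bmi)
        row: dict = {
            "id": rec.id,
            "bmi": bmi,
            "bmi_category": category,
            "obesity": obese,
            "glim": int(diagnostics.glim(rec, bmi)),
        }
        dyn = None
        if rec.hgs is not None:
            dyn = diagnostics.dynapenia(rec.hgs, rec.age, rec.sex, grip_table)
        row["dynapenia"] = dyn
        values = {**rec.model_dump(), **derived.model_dump()}
        for name, cs in cutoff_sets.items():
            kind = "myosteatosis" if cs.biomarker == "l3_smd" else "atrophy"
            value = values.get(cs.biomarker)
            if value is None:
                row[f"{kind}_{name}"] = None
                if kind == "atrophy":
                    row[f"sarcopenia_{name}"] = None
                continue
            flag = cs.classify(value, rec.sex, bmi=bmi, age=rec.age)
            row[f"{kind}_{name}"] = flag
            if kind == "atrophy":
                row[f"sarcopenia_{name}"] = (
                    diagnostics.sarcopenia(flag, dyn) if dyn is not None else None
                )
        rows.append(row)
    return pd.DataFrame(rows).convert_dtypes()


def prevalence_table(flags: pd.DataFrame) -> pd.DataFrame:
    """n/N and percent positive for every boolean flag column."""
    rows = []
    for col in flags.columns:
        series = flags[col]
        if series.dropna().isin([True, False]).all() and series.notna().any():
            vals = series.dropna().astype(bool)
            n_pos, n, pct = diagnostics.prevalence(list(vals))
            rows.append({"definition": col, "positives": n_pos, "n": n,
                         "percent": pct})
    return pd.DataFrame(rows)
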