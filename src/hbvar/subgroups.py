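"""Stratified CV estimation over covariates and derived measurement features.

Subgroup analyses repeat the variance-components fit on subsets of patients:
each stratum keeps all records of its member patients. Groups below a
minimum size floor (default 100 patients) are suppressed — reported with
counts but no estimate — because the CV interval is too wide to be
informative there. Cross-classification takes the Cartesian product of up to
four specs, with the suppression rule applied cellwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SpecificationError
from .variance_cv import CVEstimate, cv_from_components, fit_components_moments, fit_components_reml

__all__ = [
    "SubgroupSpec",
    "SubgroupResult",
    "derive_features",
    "stratified_cv",
    "stratified_cv_by_status",
    "cross_classified_cv",
    "results_table",
]

#: Decade age bands used for reporting (band label by upper edge).
AGE_BAND_EDGES = [10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
BMI_BAND_EDGES = [18.5, 25.0, 30.0, 35.0]
BMI_BAND_LABELS = ["<18.5", "18.5 to <25", "25 to <30", "30 to <35", ">35"]

MISSING = "missing"


@dataclass
class SubgroupSpec:
    """One stratification: a variable plus optional binning.

    ``variable`` may be any covariate column or derived feature. For numeric
    variables supply ``bin_edges`` (left-closed bins); for categoricals an
    optional ``categories`` list fixes the reporting order.
    """

    variable: str
    bin_edges: list | None = None
    categories: list | None = None
    min_group_size: int = 100

    def validate(self) -> None:
        if self.min_group_size < 2:
            raise SpecificationError("min_group_size: must be >= 2")
        if self.bin_edges is not None:
            edges = list(self.bin_edges)
            if sorted(edges) != edges or len(set(edges)) != len(edges):
                raise SpecificationError(f"{self.variable}: bin_edges must be strictly increasing")


@dataclass
class SubgroupResult:
    variable: str
    stratum: str
    n_patients: int
    n_records: int
    mean_hba1c: float | None
    estimate: CVEstimate | None
    suppressed: bool

    def to_dict(self) -> dict:
        d = {
            "variable": self.variable,
            "stratum": self.stratum,
            "n_patients": self.n_patients,
            "n_records": self.n_records,
            "mean_hba1c": self.mean_hba1c,
            "suppressed": self.suppressed,
        }
        if self.estimate is not None:
            d.update({"cv": self.estimate.cv, "ci_low": self.estimate.ci_low, "ci_high": self.estimate.ci_high})
        else:
            d.update({"cv": None, "ci_low": None, "ci_high": None})
        return d


def _age_band(age: pd.Series) -> pd.Series:
    edges = AGE_BAND_EDGES
    labels = [f"<={edges[0]}"] + [f"{lo + 1}-{hi}" for lo, hi in zip(edges[:-1], edges[1:])] + [f">{edges[-1]}"]
    idx = np.digitize(age.to_numpy(dtype=float), [e + 0.5 for e in edges])
    return pd.Series(np.asarray(labels, dtype=object)[idx], index=age.index)


def _bmi_band(bmi: pd.Series) -> pd.Series:
    v = pd.to_numeric(bmi, errors="coerce")
    idx = np.digitize(v.to_numpy(dtype=float), BMI_BAND_EDGES)
    out = pd.Series(np.asarray(BMI_BAND_LABELS, dtype=object)[idx], index=bmi.index)
    out[v.isna()] = MISSING
    return out


def derive_features(results: pd.DataFrame, covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-patient feature table for stratification.

    Computes measurement count, mean/median HbA1c, median gap in days between
    consecutive measurements, first calendar year and quarter, and (when
    covariates are supplied) age and BMI bands; covariate columns are merged
    through so any of them can be stratified on directly. Age is age at first
    measurement.
    """
    r = results.sort_values(["patient_id", "date"], kind="stable")
    g = r.groupby("patient_id", sort=False)
    gaps = g["date"].apply(lambda d: float(np.median(np.diff(d.to_numpy()).astype("timedelta64[D]").astype(float))) if len(d) > 1 else np.nan)
    feats = pd.DataFrame(
        {
            "n_measurements": g["value"].size(),
            "mean_hba1c": g["value"].mean(),
            "median_hba1c": g["value"].median(),
            "median_gap_days": gaps,
            "first_year": g["date"].min().dt.year,
            "first_quarter": g["date"].min().dt.quarter,
        }
    ).reset_index()
    if covariates is not None and not covariates.empty:
        feats = feats.merge(covariates, on="patient_id", how="left")
        if "age" in feats.columns:
            feats["age_band"] = _age_band(feats["age"])
        if "bmi" in feats.columns:
            feats["bmi_band"] = _bmi_band(feats["bmi"])
    return feats


def _assign(features: pd.DataFrame, spec: SubgroupSpec) -> pd.Series:
    spec.validate()
    if spec.variable not in features.columns:
        raise SpecificationError(f"unknown subgroup variable {spec.variable!r}")
    col = features[spec.variable]
    if spec.bin_edges is not None:
        edges = list(spec.bin_edges)
        v = pd.to_numeric(col, errors="coerce")
        binned = pd.cut(v, bins=edges, right=False)
        out = binned.astype(object).map(lambda iv: f"[{iv.left:g}, {iv.right:g})" if pd.notna(iv) else MISSING)
        out[v.isna()] = MISSING
        return pd.Series(out, index=features.index, dtype=object)
    out = col.astype(object).where(col.notna(), MISSING)
    return out


def _fit_group(results: pd.DataFrame, method: str, level: float):
    fit = fit_components_reml if method == "reml" else fit_components_moments
    vc = fit(results)
    return cv_from_components(vc, level=level)


def stratified_cv(results: pd.DataFrame, features: pd.DataFrame, spec: SubgroupSpec,
                  method: str = "reml", level: float = 0.95) -> list:
    """Repeat the whole-cohort CV fit within each stratum of ``spec``.

    Missing values form their own reported category; strata under the floor
    are returned suppressed, with counts but no estimate.
    """
    labels = _assign(features, spec)
    by_patient = dict(zip(features["patient_id"], labels))
    assigned = results["patient_id"].map(by_patient)
    out = []
    cats = spec.categories or sorted(labels.dropna().unique(), key=str)
    for cat in cats:
        pids = features.loc[labels == cat, "patient_id"]
        sub = results.loc[assigned == cat]
        n_pat = int(pids.nunique())
        n_rec = int(len(sub))
        if n_pat < spec.min_group_size:
            out.append(SubgroupResult(spec.variable, str(cat), n_pat, n_rec, None, None, True))
            continue
        est = _fit_group(sub, method, level)
        out.append(
            SubgroupResult(
                spec.variable, str(cat), n_pat, n_rec, float(sub["value"].mean()), est, False
            )
        )
    return out


def stratified_cv_by_status(results: pd.DataFrame, status_col: str = "diabetic_status",
                            min_run: int = 4, method: str = "reml", level: float = 0.95,
                            min_group_size: int = 100) -> list:
    """Status stratification robust to patients whose status changes.

    Requires a record-level status column. Each patient's chronologically
    ordered records are split into runs of constant status; a patient
    contributes a run to that status stratum only if the run has at least
    ``min_run`` results, otherwise they are excluded from this analysis.
    """
    if status_col not in results.columns:
        raise SpecificationError(f"unknown record-level status column {status_col!r}")
    r = results.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)
    change = (r[status_col] != r[status_col].shift()) | (r["patient_id"] != r["patient_id"].shift())
    run_id = change.cumsum()
    run_sizes = run_id.map(run_id.value_counts())
    kept = r.loc[run_sizes >= min_run].copy()
    # a patient may contribute several qualifying runs of the same status;
    # keep them distinct per (patient, run) for the within-patient fit
    kept["patient_id"] = kept["patient_id"].astype(str) + "#r" + run_id.loc[kept.index].astype(str)
    out = []
    for cat in sorted(kept[status_col].unique(), key=str):
        sub = kept.loc[kept[status_col] == cat]
        n_pat = int(sub["patient_id"].nunique())
        if n_pat < min_group_size:
            out.append(SubgroupResult(status_col, str(cat), n_pat, len(sub), None, None, True))
            continue
        est = _fit_group(sub, method, level)
        out.append(SubgroupResult(status_col, str(cat), n_pat, len(sub), float(sub["value"].mean()), est, False))
    return out


def cross_classified_cv(results: pd.DataFrame, features: pd.DataFrame, specs: list,
                        method: str = "reml", level: float = 0.95,
                        drop_missing: bool = True) -> pd.DataFrame:
    """Cartesian-product stratification over up to four specs.

    Returns a long, heat-map-ready table with one row per cell. Patients with
    a missing value on any spec variable are excluded when ``drop_missing``
    (multi-variable analyses use complete cases only).
    """
    if not 1 <= len(specs) <= 4:
        raise SpecificationError("cross-classification supports 1 to 4 specs")
    assignments = [_assign(features, s) for s in specs]
    floor = max(s.min_group_size for s in specs)
    frame = pd.DataFrame({s.variable: a for s, a in zip(specs, assignments)})
    frame["patient_id"] = features["patient_id"].to_numpy()
    if drop_missing:
        frame = frame[(frame[[s.variable for s in specs]] != MISSING).all(axis=1)]
    cats = [s.categories or sorted(frame[s.variable].unique(), key=str) for s in specs]
    cell_of = frame.set_index("patient_id")[[s.variable for s in specs]]
    assigned = results.merge(cell_of, left_on="patient_id", right_index=True, how="inner")
    rows = []
    grid = pd.MultiIndex.from_product(cats, names=[s.variable for s in specs])
    grouped = {}
    for key, sub in assigned.groupby([s.variable for s in specs], sort=False):
        grouped[key if isinstance(key, tuple) else (key,)] = sub
    for combo in grid:
        combo = combo if isinstance(combo, tuple) else (combo,)
        sub = grouped.get(combo)
        if sub is None:
            sub = assigned.iloc[0:0]
        n_pat = int(sub["patient_id"].nunique())
        row = dict(zip([s.variable for s in specs], combo if isinstance(combo, tuple) else (combo,)))
        row.update({"n_patients": n_pat, "n_records": len(sub)})
        if n_pat < floor:
            row.update({"mean_hba1c": None, "cv": None, "ci_low": None, "ci_high": None, "suppressed": True})
        else:
            est = _fit_group(sub[["patient_id", "date", "value"]], method, level)
            row.update(
                {
                    "mean_hba1c": float(sub["value"].mean()),
                    "cv": est.cv,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "suppressed": False,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def results_table(results: list) -> pd.DataFrame:
    """Flatten a list of SubgroupResult into a delimited-text-ready table."""
    return pd.DataFrame([r.to_dict() for r in results])
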