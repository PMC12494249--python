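"""Cleaning cascade for longitudinal HbA1c extracts.

The rules mirror standard practice for routinely collected laboratory data:

1. keep a single unit system (mmol/mol) — percent-tagged results are excluded
   rather than converted, because the affine unit conversion changes relative
   dispersion;
2. drop implausible values outside the (20.1, 195.1) mmol/mol window, noting
   that sub-20.1 entries are typically percent values mis-recorded under
   mmol/mol units;
3. keep only the first result of any same-patient same-day group (later ones
   are almost always transcription duplicates);
4. remove patients reporting one identical value on four or more distinct
   dates (overwhelmingly duplicated records, not biology);
5. require at least four remaining measurements per patient.

The stage order is fixed: record-level plausibility filters run before the
patient-level exclusions so the latter only ever see deduplicated, plausible
records. Every removal is counted at both record and patient level and the
report reconciles exactly: the cascade is idempotent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError
from .synthetic_cohort import MMOL_MOL, PERCENT, Cohort

__all__ = [
    "CleaningConfig",
    "CleaningReport",
    "filter_unit",
    "filter_range",
    "dedupe_same_day",
    "drop_identical_runs",
    "require_min_measurements",
    "recode_bmi",
    "clean",
]

STAGES = ("unit", "range_low", "range_high", "same_day_duplicate", "identical_results", "too_few_measurements")

_KNOWN_UNITS = {MMOL_MOL, PERCENT}


@dataclass
class CleaningConfig:
    unit_kept: str = MMOL_MOL
    low_cut: float = 20.1
    high_cut: float = 195.1
    min_measurements: int = 4
    identical_min_run: int = 4
    bmi_low: float = 14.0
    bmi_high: float = 70.0
    #: values are rounded to this resolution before the identical-results
    #: comparison (typical laboratory reporting resolution).
    value_resolution: float = 0.1

    def validate(self) -> None:
        if self.low_cut >= self.high_cut:
            raise ConfigError("low_cut: must be below high_cut")
        if self.min_measurements < 2:
            raise ConfigError("min_measurements: must be >= 2")
        if self.identical_min_run < 2:
            raise ConfigError("identical_min_run: must be >= 2")
        if self.bmi_low >= self.bmi_high:
            raise ConfigError("bmi_low: must be below bmi_high")
        if self.value_resolution <= 0:
            raise ConfigError("value_resolution: must be > 0")


@dataclass
class CleaningReport:
    """Per-rule removal accounting for one pass of the cascade.

    ``records_removed``/``patients_removed`` are keyed by stage name. A
    patient is attributed to the stage at which their last record (or their
    whole record, for patient-level rules) disappeared.
    """

    records_in: int = 0
    patients_in: int = 0
    records_removed: dict = field(default_factory=lambda: {s: 0 for s in STAGES})
    patients_removed: dict = field(default_factory=lambda: {s: 0 for s in STAGES})
    bmi_recoded_missing: int = 0
    records_out: int = 0
    patients_out: int = 0

    def check_conservation(self) -> None:
        rec = self.records_out + sum(self.records_removed.values())
        if rec != self.records_in:
            raise AssertionError(f"record conservation violated: {rec} != {self.records_in}")
        pat = self.patients_out + sum(self.patients_removed.values())
        if pat != self.patients_in:
            raise AssertionError(f"patient conservation violated: {pat} != {self.patients_in}")

    def to_dict(self) -> dict:
        return {
            "records_in": self.records_in,
            "patients_in": self.patients_in,
            "records_removed": dict(self.records_removed),
            "patients_removed": dict(self.patients_removed),
            "bmi_recoded_missing": self.bmi_recoded_missing,
            "records_out": self.records_out,
            "patients_out": self.patients_out,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def summary(self) -> str:
        lines = [
            f"records in:  {self.records_in} ({self.patients_in} patients)",
        ]
        for s in STAGES:
            lines.append(
                f"  - {s}: {self.records_removed[s]} records, {self.patients_removed[s]} patients removed"
            )
        lines.append(f"BMI recoded missing: {self.bmi_recoded_missing}")
        lines.append(f"records out: {self.records_out} ({self.patients_out} patients)")
        return "\n".join(lines)


def filter_unit(results: pd.DataFrame, config: CleaningConfig | None = None):
    """Keep only records in the retained unit system; count removals."""
    config = config or CleaningConfig()
    units = results["unit"]
    unknown = ~units.isin(_KNOWN_UNITS)
    if unknown.any():
        row = results.index[unknown][0]
        raise DataError(f"unknown unit tag {units.loc[row]!r} at row {row}")
    keep = units == config.unit_kept
    return results.loc[keep], int((~keep).sum())


def filter_range(results: pd.DataFrame, config: CleaningConfig | None = None):
    """Drop values strictly below ``low_cut`` or strictly above ``high_cut``.

    Boundary values survive: the exclusions are strict inequalities, so the
    retained range is inclusive of 20.1 and 195.1 mmol/mol.
    """
    config = config or CleaningConfig()
    v = results["value"]
    low = v < config.low_cut
    high = v > config.high_cut
    keep = ~(low | high)
    return results.loc[keep], int(low.sum()), int(high.sum())


def dedupe_same_day(results: pd.DataFrame):
    """Within each (patient, date) group keep the first record in input order."""
    dup = results.duplicated(subset=["patient_id", "date"], keep="first")
    return results.loc[~dup], int(dup.sum())


def drop_identical_runs(results: pd.DataFrame, config: CleaningConfig | None = None):
    """Remove patients with one value repeated on >= ``identical_min_run``
    distinct dates (after rounding to the reporting resolution)."""
    config = config or CleaningConfig()
    if results.empty:
        return results, 0
    res = config.value_resolution
    rounded = np.round(results["value"].to_numpy() / res) * res
    key = pd.DataFrame(
        {"patient_id": results["patient_id"].to_numpy(), "v": np.round(rounded, 6), "date": results["date"].to_numpy()}
    )
    runs = key.groupby(["patient_id", "v"], sort=False)["date"].nunique()
    bad_patients = runs[runs >= config.identical_min_run].index.get_level_values(0).unique()
    keep = ~results["patient_id"].isin(bad_patients)
    return results.loc[keep], int(len(bad_patients))


def require_min_measurements(results: pd.DataFrame, config: CleaningConfig | None = None):
    """Remove patients with fewer than ``min_measurements`` remaining records."""
    config = config or CleaningConfig()
    if results.empty:
        return results, 0
    counts = results.groupby("patient_id", sort=False)["value"].size()
    bad = counts[counts < config.min_measurements].index
    keep = ~results["patient_id"].isin(bad)
    return results.loc[keep], int(len(bad))


def recode_bmi(covariates: pd.DataFrame, config: CleaningConfig | None = None):
    """Set BMI strictly below ``bmi_low`` or strictly above ``bmi_high`` to
    missing; boundary values are kept."""
    config = config or CleaningConfig()
    if "bmi" not in covariates.columns:
        return covariates, 0
    out = covariates.copy()
    bmi = pd.to_numeric(out["bmi"], errors="coerce")
    bad = (bmi < config.bmi_low) | (bmi > config.bmi_high)
    out["bmi"] = bmi.mask(bad)
    return out, int(bad.sum())


def _npatients(results: pd.DataFrame) -> int:
    return int(results["patient_id"].nunique())


def clean(results: pd.DataFrame, covariates: pd.DataFrame | None = None,
          config: CleaningConfig | None = None):
    """Run the full cascade in fixed order and reconcile all counts.

    Returns ``(results, covariates, report)``. Patients who lose their last
    record at a record-level stage are attributed to that stage.
    """
    config = config or CleaningConfig()
    config.validate()
    if covariates is None:
        covariates = pd.DataFrame({"patient_id": results["patient_id"].unique()})

    report = CleaningReport(records_in=len(results), patients_in=_npatients(results))

    def account_patients(before: int, after_frame: pd.DataFrame, stage: str, explicit: int | None = None):
        after = _npatients(after_frame)
        report.patients_removed[stage] = before - after if explicit is None else explicit
        return after

    npat = report.patients_in

    out, n_unit = filter_unit(results, config)
    report.records_removed["unit"] = n_unit
    npat = account_patients(npat, out, "unit")

    before = len(out)
    out, n_low, n_high = filter_range(out, config)
    report.records_removed["range_low"] = n_low
    report.records_removed["range_high"] = n_high
    # attribute patient loss across the two range rules jointly to the low
    # side unless only high values were removed
    lost = npat - _npatients(out)
    if lost:
        report.patients_removed["range_low" if n_low else "range_high"] = lost
    npat = _npatients(out)

    out, n_dup = dedupe_same_day(out)
    report.records_removed["same_day_duplicate"] = n_dup
    npat = account_patients(npat, out, "same_day_duplicate")

    before_records = len(out)
    out, n_ident_pat = drop_identical_runs(out, config)
    report.records_removed["identical_results"] = before_records - len(out)
    report.patients_removed["identical_results"] = n_ident_pat
    npat -= n_ident_pat

    before_records = len(out)
    out, n_few = require_min_measurements(out, config)
    report.records_removed["too_few_measurements"] = before_records - len(out)
    report.patients_removed["too_few_measurements"] = n_few

    report.records_out = len(out)
    report.patients_out = _npatients(out)

    cov_out, n_bmi = recode_bmi(covariates, config)
    report.bmi_recoded_missing = n_bmi
    cov_out = cov_out[cov_out["patient_id"].isin(out["patient_id"].unique())]

    report.check_conservation()
    return out.reset_index(drop=True), cov_out.reset_index(drop=True), report
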