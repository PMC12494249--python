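"""Seeded generator for synthetic longitudinal HbA1c cohorts.

Real primary-care laboratory extracts are not redistributable, so every
downstream stage of this package is exercised against cohorts drawn from a
generative model with the same statistical skeleton: per-patient latent true
means stratified by diabetic status, constant within-patient coefficient of
variation (CV) around that mean, a long-tailed visit-count law, and the data
quality defects routinely seen in recorded results — percent values
mis-recorded under mmol/mol units, exact same-day duplicates, implausibly
high entries, and patients whose record holds many copies of one value.

The generator is fully deterministic given ``(seed, config)``: a single
``numpy.random.Generator`` drives every draw in a fixed order, so identical
configurations reproduce byte-identical tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError

__all__ = [
    "VisitCountLaw",
    "VisitSpacingLaw",
    "StratumSpec",
    "SimConfig",
    "Cohort",
    "TruthRecord",
    "TruthSummary",
    "table2_strata",
    "default_sim_config",
    "generate_cohort",
    "truth_summary",
    "write_cohort",
    "read_cohort",
]

MMOL_MOL = "mmol/mol"
PERCENT = "percent"

#: Plausibility window on the mmol/mol scale; latent true means are truncated
#: to this range and injected implausible values are drawn strictly above it.
PLAUSIBLE_LOW = 20.1
PLAUSIBLE_HIGH = 195.1

# z-score of the upper quartile of a standard normal; converts an IQR into a
# log-normal sigma.
_Z_75 = 0.6744897501960817

DEFAULT_COVARIATE_LAWS: dict = {
    "sex": {"categories": ["male", "female"], "p": [0.517, 0.483]},
    "age": {"dist": "normal", "mean": 68.0, "sd": 16.0, "low": 1, "high": 105},
    "ethnicity": {
        "categories": ["white", "south_asian", "black", "mixed", "other", "missing"],
        "p": [0.518, 0.043, 0.019, 0.004, 0.014, 0.402],
    },
    "deprivation": {
        "categories": ["1", "2", "3", "4", "5", "missing"],
        "p": [0.176, 0.169, 0.177, 0.164, 0.124, 0.190],
    },
    "bmi": {"dist": "normal", "mean": 28.5, "sd": 5.8, "low": 10.0, "high": 80.0},
    "smoking": {"categories": ["never", "ex", "current", "missing"], "p": [0.45, 0.30, 0.15, 0.10]},
    "alcohol": {"categories": ["non_drinker", "current", "ex", "missing"], "p": [0.20, 0.60, 0.10, 0.10]},
    "diabetes_medication": {"categories": [0, 1], "p": [0.60, 0.40]},
    "hypertension": {"categories": [0, 1], "p": [0.65, 0.35]},
    "ihd": {"categories": [0, 1], "p": [0.88, 0.12]},
    "cancer": {"categories": [0, 1], "p": [0.90, 0.10]},
    "hypothyroidism": {"categories": [0, 1], "p": [0.92, 0.08]},
}


@dataclass
class VisitCountLaw:
    """Law for the number of HbA1c measurements per patient.

    ``lognormal`` discretizes a log-normal by rounding; its two parameters are
    the target median and interquartile range on the count scale, matching how
    routine-care visit counts are usually summarised. ``fixed`` gives every
    patient exactly ``n`` visits (useful for balanced designs in tests).
    """

    name: str = "lognormal"
    median: float = 11.0
    iqr: tuple = (7.0, 18.0)
    n: int | None = None
    min_visits: int = 1

    def validate(self) -> None:
        if self.name not in ("lognormal", "fixed"):
            raise ConfigError(f"visit_count_law.name: unknown law {self.name!r}")
        if self.name == "fixed" and (self.n is None or self.n < 1):
            raise ConfigError("visit_count_law.n: fixed law requires n >= 1")
        if self.name == "lognormal":
            lo, hi = self.iqr
            if not (0 < lo < hi) or self.median <= 0:
                raise ConfigError("visit_count_law: require 0 < iqr[0] < iqr[1] and median > 0")
        if self.min_visits < 1:
            raise ConfigError("visit_count_law.min_visits: must be >= 1")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.name == "fixed":
            return np.full(size, int(self.n), dtype=np.int64)
        sigma = math.log(self.iqr[1] / self.iqr[0]) / (2.0 * _Z_75)
        draws = rng.lognormal(mean=math.log(self.median), sigma=sigma, size=size)
        return np.maximum(np.rint(draws).astype(np.int64), self.min_visits)


@dataclass
class VisitSpacingLaw:
    """Law for the gap, in days, between consecutive measurements."""

    name: str = "uniform"
    low: int = 30
    high: int = 365
    gap: int | None = None  # for name == "fixed"

    def validate(self) -> None:
        if self.name not in ("uniform", "fixed"):
            raise ConfigError(f"visit_spacing_days.name: unknown law {self.name!r}")
        if self.name == "uniform" and not (1 <= self.low <= self.high):
            raise ConfigError("visit_spacing_days: require 1 <= low <= high")
        if self.name == "fixed" and (self.gap is None or self.gap < 1):
            raise ConfigError("visit_spacing_days.gap: fixed law requires gap >= 1")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.name == "fixed":
            return np.full(size, int(self.gap), dtype=np.int64)
        return rng.integers(self.low, self.high + 1, size=size)


@dataclass
class StratumSpec:
    """One diabetic-status stratum of the cohort.

    ``true_mean_center``/``true_mean_sd`` parameterise the between-patient
    normal law of latent true means (mmol/mol), truncated to the plausible
    window; ``within_cv`` is the within-patient coefficient of variation, so
    a patient with true mean mu has measurement SD ``within_cv * mu``.
    """

    label: str
    weight: float
    true_mean_center: float
    true_mean_sd: float
    within_cv: float
    medication_rate: float = 0.0
    covariate_laws: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.weight < 0:
            raise ConfigError(f"strata[{self.label}].weight: must be >= 0")
        if self.true_mean_center <= 0:
            raise ConfigError(f"strata[{self.label}].true_mean_center: must be > 0")
        if self.true_mean_sd < 0:
            raise ConfigError(f"strata[{self.label}].true_mean_sd: must be >= 0")
        if self.within_cv < 0:
            raise ConfigError(f"strata[{self.label}].within_cv: must be >= 0")
        if not 0.0 <= self.medication_rate <= 1.0:
            raise ConfigError(f"strata[{self.label}].medication_rate: must be in [0,1]")


_ERROR_KEYS = ("percent_unit_error", "same_day_duplicate", "implausible_high", "identical_run")


@dataclass
class SimConfig:
    """Full parameterisation of one synthetic cohort draw."""

    seed: int
    n_patients: int
    strata: list
    visit_count_law: VisitCountLaw = field(default_factory=VisitCountLaw)
    visit_spacing_days: VisitSpacingLaw = field(default_factory=VisitSpacingLaw)
    error_rates: dict = field(default_factory=dict)
    date_range: tuple = ("2010-01-01", "2019-12-31")
    #: Reported results are rounded to this resolution (mmol/mol); ``None``
    #: emits raw floating-point draws.
    reporting_resolution: float | None = 0.1

    def __post_init__(self) -> None:
        full = {k: 0.0 for k in _ERROR_KEYS}
        full.update(self.error_rates)
        self.error_rates = full

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients: must be >= 1")
        if not self.strata:
            raise ConfigError("strata: at least one stratum required")
        for s in self.strata:
            s.validate()
        total = sum(s.weight for s in self.strata)
        if abs(total - 1.0) > 1e-8:
            raise ConfigError(f"strata weights: must sum to 1 (got {total:.6f})")
        for key, rate in self.error_rates.items():
            if key not in _ERROR_KEYS:
                raise ConfigError(f"error_rates.{key}: unknown error mode")
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"error_rates.{key}: must be in [0,1]")
        self.visit_count_law.validate()
        self.visit_spacing_days.validate()
        start, end = (pd.Timestamp(d) for d in self.date_range)
        if start >= end:
            raise ConfigError("date_range: start must precede end")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if d.get("strata") == "table2":
            d["strata"] = table2_strata()
        else:
            d["strata"] = [StratumSpec(**s) if isinstance(s, dict) else s for s in d.get("strata", [])]
        if isinstance(d.get("visit_count_law"), dict):
            law = dict(d["visit_count_law"])
            if "iqr" in law:
                law["iqr"] = tuple(law["iqr"])
            d["visit_count_law"] = VisitCountLaw(**law)
        if isinstance(d.get("visit_spacing_days"), dict):
            d["visit_spacing_days"] = VisitSpacingLaw(**d["visit_spacing_days"])
        if "date_range" in d:
            d["date_range"] = tuple(d["date_range"])
        return cls(**d)


class Cohort(NamedTuple):
    """Long-format results plus one-row-per-patient covariates."""

    results: pd.DataFrame
    covariates: pd.DataFrame


@dataclass
class TruthRecord:
    """Latent truth and injected-error bookkeeping for a generated cohort.

    Row indices refer to positional indices of ``Cohort.results``.
    """

    patients: pd.DataFrame  # patient_id, stratum, true_mean, n_visits
    unit_error_rows: np.ndarray
    implausible_rows: np.ndarray
    duplicate_rows: np.ndarray
    identical_run_patients: list

    def to_json(self, path) -> None:
        payload = {
            "patients": self.patients.to_dict(orient="list"),
            "unit_error_rows": self.unit_error_rows.tolist(),
            "implausible_rows": self.implausible_rows.tolist(),
            "duplicate_rows": self.duplicate_rows.tolist(),
            "identical_run_patients": list(self.identical_run_patients),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        payload = json.loads(Path(path).read_text())
        return cls(
            patients=pd.DataFrame(payload["patients"]),
            unit_error_rows=np.asarray(payload["unit_error_rows"], dtype=np.int64),
            implausible_rows=np.asarray(payload["implausible_rows"], dtype=np.int64),
            duplicate_rows=np.asarray(payload["duplicate_rows"], dtype=np.int64),
            identical_run_patients=payload["identical_run_patients"],
        )


@dataclass
class TruthSummary:
    strata: pd.DataFrame  # index: stratum; columns: n_patients, true_mean_avg
    n_unit_errors: int
    n_implausible: int
    n_duplicates: int
    n_identical_run_patients: int


def table2_strata() -> list:
    """Diabetic-status strata matching the study population's marginals.

    Weights are the published group fractions, centers the published group
    mean HbA1c, and within-patient CVs the published group CV_T. Between-
    patient SDs are not published and are package choices (see methods note).
    """
    raw = [
        # label, n, mean, within_cv, true_mean_sd, medication_rate
        ("no_dm", 148870, 38.24, 0.091, 3.5, 0.01),
        ("prediabetes", 73649, 48.74, 0.180, 4.0, 0.05),
        ("t1dm", 33404, 70.17, 0.157, 14.0, 0.98),
        ("t2dm", 329038, 58.70, 0.194, 12.0, 0.75),
    ]
    total = sum(n for _, n, *_ in raw)
    return [
        StratumSpec(
            label=label,
            weight=n / total,
            true_mean_center=mean,
            true_mean_sd=sd,
            within_cv=cv,
            medication_rate=med,
        )
        for label, n, mean, cv, sd, med in raw
    ]


def default_sim_config(seed: int = 0, n_patients: int = 5000, **overrides) -> SimConfig:
    """Study-condition defaults: Table-2 strata, median-11 visit law, and the
    recorded-data error modes at low rates."""
    cfg = SimConfig(
        seed=seed,
        n_patients=n_patients,
        strata=table2_strata(),
        error_rates={
            "percent_unit_error": 0.002,
            "same_day_duplicate": 0.002,
            "implausible_high": 0.0001,
            "identical_run": 0.001,
        },
        **overrides,
    )
    cfg.validate()
    return cfg


def _draw_truncnorm(rng, center, sd, low, high, size):
    """Normal draws truncated to (low, high) by resampling."""
    out = rng.normal(center, sd, size=size)
    if sd == 0:
        return np.clip(out, low, high)
    for _ in range(1000):
        bad = (out <= low) | (out >= high)
        if not bad.any():
            break
        out[bad] = rng.normal(center, sd, size=int(bad.sum()))
    return np.clip(out, low + 1e-9, high - 1e-9)


def _draw_covariate(rng, law, size):
    if "categories" in law:
        idx = rng.choice(len(law["categories"]), size=size, p=law["p"])
        return np.asarray(law["categories"], dtype=object)[idx]
    if law.get("dist") == "normal":
        vals = rng.normal(law["mean"], law["sd"], size=size)
        return np.clip(vals, law["low"], law["high"])
    raise ConfigError(f"covariate law: unsupported specification {law!r}")


def generate_cohort(config: SimConfig) -> tuple[Cohort, TruthRecord]:
    """Draw one synthetic cohort.

    Returns the long results table (patient_id, date, value, unit), the
    per-patient covariate table, and a :class:`TruthRecord` linking every
    injected defect back to its rows.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    strata = config.strata
    rates = config.error_rates

    weights = np.array([s.weight for s in strata], dtype=float)
    weights = weights / weights.sum()
    stratum_idx = rng.choice(len(strata), size=n, p=weights)

    centers = np.array([s.true_mean_center for s in strata])
    sds = np.array([s.true_mean_sd for s in strata])
    cvs = np.array([s.within_cv for s in strata])

    true_mean = np.empty(n)
    for j, s in enumerate(strata):
        mask = stratum_idx == j
        m = int(mask.sum())
        if m:
            true_mean[mask] = _draw_truncnorm(
                rng, centers[j], sds[j], PLAUSIBLE_LOW, PLAUSIBLE_HIGH, m
            )

    n_visits = config.visit_count_law.sample(rng, n)

    # Patients flagged for an identical-results run keep >= 4 visits.
    identical_mask = rng.random(n) < rates["identical_run"]
    n_visits = np.where(identical_mask, np.maximum(n_visits, 4), n_visits)

    total_rows = int(n_visits.sum())
    row_patient = np.repeat(np.arange(n), n_visits)
    first_pos = np.concatenate(([0], np.cumsum(n_visits)[:-1]))

    # Dates: first visit uniform over date_range, then i.i.d. gaps.
    start = pd.Timestamp(config.date_range[0])
    end = pd.Timestamp(config.date_range[1])
    span = (end - start).days
    first_offset = rng.integers(0, span + 1, size=n)
    gaps = config.visit_spacing_days.sample(rng, total_rows)
    gaps[first_pos] = first_offset
    cum = np.cumsum(gaps)
    day = cum - np.repeat(cum[first_pos], n_visits) + np.repeat(first_offset, n_visits)

    # Clean values: Normal(mu, cv*mu), truncated at > 0 by resampling.
    mu_row = true_mean[row_patient]
    sd_row = cvs[stratum_idx][row_patient] * mu_row
    values = rng.normal(mu_row, sd_row)
    for _ in range(100):
        bad = values <= 0
        if not bad.any():
            break
        values[bad] = rng.normal(mu_row[bad], sd_row[bad])
    values = np.maximum(values, 1e-6)

    # Identical-run patients: every visit carries one repeated value.
    ident_row = identical_mask[row_patient]
    if ident_row.any():
        rep = values[first_pos]  # one value per patient (their first draw)
        values[ident_row] = np.repeat(rep, n_visits)[ident_row]

    res = config.reporting_resolution
    if res:
        values = np.round(values / res) * res

    # Row-level recording errors; identical-run patients are left untouched so
    # their defining defect stays intact.
    eligible = ~ident_row
    unit_err = eligible & (rng.random(total_rows) < rates["percent_unit_error"])
    if unit_err.any():
        k = int(unit_err.sum())
        pct = np.clip(rng.normal(7.7, 1.2, size=k), 3.0, 15.0)
        if res:
            pct = np.round(pct / res) * res
        values[unit_err] = pct
    implausible = eligible & ~unit_err & (rng.random(total_rows) < rates["implausible_high"])
    if implausible.any():
        k = int(implausible.sum())
        high = rng.uniform(PLAUSIBLE_HIGH + 0.1, 500.0, size=k)
        if res:
            high = np.round(high / res) * res
        values[implausible] = high

    # Same-day duplicates: exact copies ordered directly after their source
    # row, so downstream "first result of the day" keeps the original.
    dup_src = np.flatnonzero(rng.random(total_rows) < rates["same_day_duplicate"])

    def _with_dups(arr):
        return np.concatenate([arr, arr[dup_src]]) if dup_src.size else arr

    all_patient = _with_dups(row_patient)
    all_day = _with_dups(day)
    all_values = _with_dups(values)
    all_unit_err = _with_dups(unit_err)
    all_implausible = _with_dups(implausible)
    is_dup = np.concatenate(
        [np.zeros(total_rows, dtype=np.int8), np.ones(dup_src.size, dtype=np.int8)]
    ) if dup_src.size else np.zeros(total_rows, dtype=np.int8)

    order = np.lexsort((is_dup, all_day, all_patient))
    all_patient = all_patient[order]
    all_day = all_day[order]
    all_values = all_values[order]
    all_unit_err = all_unit_err[order]
    all_implausible = all_implausible[order]
    is_dup = is_dup[order]

    pid_str = np.array([f"P{i:06d}" for i in range(n)], dtype=object)
    results = pd.DataFrame(
        {
            "patient_id": pid_str[all_patient],
            "date": start.as_unit("ns").to_datetime64() + all_day.astype("timedelta64[D]"),
            "value": all_values,
            "unit": MMOL_MOL,
        }
    )
    dup_rows = np.flatnonzero(is_dup == 1)
    unit_error_rows = np.flatnonzero(all_unit_err)
    implausible_rows = np.flatnonzero(all_implausible)

    # Covariates, one row per patient. Stratum-level overrides win over the
    # package defaults; medication comes from the stratum rate.
    cov: dict = {"patient_id": pid_str, "diabetic_status": np.array([strata[j].label for j in stratum_idx], dtype=object)}
    for name, default_law in DEFAULT_COVARIATE_LAWS.items():
        if name == "diabetes_medication":
            continue
        per_stratum = [s.covariate_laws.get(name, default_law) for s in strata]
        if all(law is default_law for law in per_stratum):
            cov[name] = _draw_covariate(rng, default_law, n)
        else:
            col = np.empty(n, dtype=object)
            for j, s in enumerate(strata):
                mask = stratum_idx == j
                if mask.any():
                    col[mask] = _draw_covariate(rng, per_stratum[j], int(mask.sum()))
            cov[name] = col
    med_rate = np.array([s.medication_rate for s in strata])[stratum_idx]
    cov["diabetes_medication"] = (rng.random(n) < med_rate).astype(int)
    covariates = pd.DataFrame(cov)
    for col in ("age", "bmi"):
        covariates[col] = covariates[col].astype(float)
    covariates["age"] = covariates["age"].round().astype(int)
    covariates["bmi"] = covariates["bmi"].round(1)

    truth = TruthRecord(
        patients=pd.DataFrame(
            {
                "patient_id": pid_str,
                "stratum": [strata[j].label for j in stratum_idx],
                "true_mean": true_mean,
                "n_visits": n_visits,
            }
        ),
        unit_error_rows=unit_error_rows,
        implausible_rows=implausible_rows,
        duplicate_rows=dup_rows,
        identical_run_patients=pid_str[identical_mask].tolist(),
    )
    return Cohort(results=results, covariates=covariates), truth


def truth_summary(truth: TruthRecord) -> TruthSummary:
    """Per-stratum patient counts and mean latent means, plus injected-error
    totals; the recovery tests compare estimates against this."""
    strata = (
        truth.patients.groupby("stratum")
        .agg(n_patients=("patient_id", "size"), true_mean_avg=("true_mean", "mean"))
        .sort_index()
    )
    return TruthSummary(
        strata=strata,
        n_unit_errors=int(truth.unit_error_rows.size),
        n_implausible=int(truth.implausible_rows.size),
        n_duplicates=int(truth.duplicate_rows.size),
        n_identical_run_patients=len(truth.identical_run_patients),
    )


def write_cohort(cohort: Cohort, outdir, truth: TruthRecord | None = None) -> dict:
    """Write results/covariates as CSV (ISO-8601 dates) and truth as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": outdir / "results.csv",
        "covariates": outdir / "covariates.csv",
    }
    res = cohort.results.copy()
    res["date"] = pd.to_datetime(res["date"]).dt.strftime("%Y-%m-%d")
    res.to_csv(paths["results"], index=False)
    cohort.covariates.to_csv(paths["covariates"], index=False)
    if truth is not None:
        paths["truth"] = outdir / "truth.json"
        truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def read_cohort(indir) -> Cohort:
    indir = Path(indir)
    rpath = indir / "results.csv"
    cpath = indir / "covariates.csv"
    if not rpath.exists():
        raise DataError(f"results file not found: {rpath}")
    results = pd.read_csv(rpath, parse_dates=["date"])
    covariates = pd.read_csv(cpath, dtype={"deprivation": str}) if cpath.exists() else pd.DataFrame(columns=["patient_id"])
    return Cohort(results=results, covariates=covariates)
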