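"""Decision probabilities under the normal measurement model, and the
CI-width sample-size simulation.

If a patient's true mean is mu and the total within-individual CV is cv, a
single measured result is modelled as N(mu, cv * mu). The probability that a
measurement lands at least the minimal clinically important difference
(MCID) away from the true mean is then

    P(|y - mu| >= MCID) = 2 * (1 - Phi(MCID / (cv * mu))),

the z-score construction used when judging whether an observed result can be
trusted to reflect the underlying mean. The threshold-crossing probability
answers the related diagnostic question: given a true mean on one side of a
diagnostic cut-point, how often will a single measurement land on the other
side.

``simulate_ci_width`` is the planning calculation: it repeatedly simulates
balanced cohorts around a common mean, estimates the CV and its 95% interval
through the variance-components machinery, and summarises the interval width
in absolute percentage points of CV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ConfigError, DomainError

__all__ = [
    "ClinicalQuery",
    "PrecisionSimConfig",
    "prob_beyond_mcid",
    "misclassification_prob",
    "simulate_ci_width",
]

DEFAULT_MCID = 5.5
#: default common true mean for the planning simulation (the overall cohort
#: mean HbA1c in mmol/mol)
DEFAULT_MU = 52.31


@dataclass
class ClinicalQuery:
    true_mean: float
    cv: float
    mcid: float = DEFAULT_MCID

    def validate(self) -> None:
        if self.true_mean <= 0:
            raise DomainError("true_mean: must be > 0")
        if self.cv < 0:
            raise DomainError("cv: must be >= 0")
        if self.mcid < 0:
            raise DomainError("mcid: must be >= 0")


def prob_beyond_mcid(q: ClinicalQuery) -> float:
    """P(single measurement differs from the true mean by >= MCID)."""
    q.validate()
    if q.mcid == 0:
        return 1.0
    if q.cv == 0:
        return 0.0
    return float(2.0 * stats.norm.sf(q.mcid / (q.cv * q.true_mean)))


def misclassification_prob(q: ClinicalQuery, threshold: float) -> float:
    """P(a single measurement lands on the far side of ``threshold``).

    The relevant side is chosen by the sign of mu - threshold: for a true
    mean above the cut-point this is the probability of measuring below it,
    and vice versa. At mu == threshold the probability is 1/2 by symmetry.
    """
    q.validate()
    if threshold <= 0:
        raise DomainError("threshold: must be > 0")
    if q.cv == 0:
        return 0.5 if q.true_mean == threshold else 0.0
    z = (threshold - q.true_mean) / (q.cv * q.true_mean)
    if q.true_mean >= threshold:
        return float(stats.norm.cdf(z))
    return float(stats.norm.sf(z))


@dataclass
class PrecisionSimConfig:
    cv_true: float
    n_patients: int = 100
    obs_per_patient: int = 4
    n_replicates: int = 500
    seed: int = 0
    ci_level: float = 0.95
    mu: float = DEFAULT_MU
    width_bound_pct: float = 10.0

    def validate(self) -> None:
        if self.cv_true < 0:
            raise ConfigError("cv_true: must be >= 0")
        if min(self.n_patients, self.obs_per_patient) < 1:
            raise ConfigError("n_patients/obs_per_patient: must be >= 1")
        if self.n_replicates < 100:
            raise ConfigError("n_replicates: must be >= 100")
        if not 0 < self.ci_level < 1:
            raise ConfigError("ci_level: must be in (0,1)")


def simulate_ci_width(cfg: PrecisionSimConfig) -> dict:
    """Replicate the CV estimate on balanced cohorts; summarise CI widths.

    Each replicate draws ``n_patients`` x ``obs_per_patient`` values
    N(mu, cv_true * mu) around a single common mean (the width criterion
    concerns the within-patient estimator, not between-patient structure),
    estimates the CV by pooled within-patient variance, and forms the
    chi-square interval. Widths are reported in absolute percentage points
    of CV; coverage is the fraction of replicate intervals containing
    ``cv_true``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, k, reps = cfg.n_patients, cfg.obs_per_patient, cfg.n_replicates
    sd = cfg.cv_true * cfg.mu
    y = rng.normal(cfg.mu, sd, size=(reps, n, k))
    if sd > 0:
        for _ in range(100):  # truncate at > 0 by resampling
            bad = y <= 0
            if not bad.any():
                break
            y[bad] = rng.normal(cfg.mu, sd, size=int(bad.sum()))

    df = n * (k - 1)
    ssw = ((y - y.mean(axis=2, keepdims=True)) ** 2).sum(axis=(1, 2))
    sw = np.sqrt(ssw / df)
    grand = y.mean(axis=(1, 2))
    cv_hat = sw / grand
    alpha = 1.0 - cfg.ci_level
    lo = sw * np.sqrt(df / stats.chi2.ppf(1 - alpha / 2, df)) / grand
    hi = sw * np.sqrt(df / stats.chi2.ppf(alpha / 2, df)) / grand
    width_pct = (hi - lo) * 100.0
    return {
        "median_width_pct": float(np.median(width_pct)),
        "p95_width_pct": float(np.quantile(width_pct, 0.95)),
        "frac_within_bound": float((width_pct < cfg.width_bound_pct).mean()),
        "coverage": float(((lo <= cfg.cv_true) & (cfg.cv_true <= hi)).mean()),
        "mean_cv_hat": float(cv_hat.mean()),
        "n_replicates": reps,
    }
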