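"""Within-individual coefficient of variation from repeated measures.

The measurement model is the intercept-only random-intercept (one-way random
effects) model

    y_ij = mu + b_i + e_ij,   b_i ~ N(0, sigma_b^2),   e_ij ~ N(0, sigma_w^2),

for patient i = 1..k with n_i repeated results. The quantity of interest is
the total within-individual coefficient of variation

    CV_T = sigma_w / mu,

expressed as a decimal fraction. Two estimators of the variance components
are provided: the unbalanced one-way ANOVA method-of-moments estimator (which
doubles as a brute-force oracle) and restricted maximum likelihood (REML).
For this model the REML criterion profiles down to one dimension in the
variance ratio lambda = sigma_b^2 / sigma_w^2, which is optimised directly —
no general mixed-model machinery is required, and on balanced designs with
interior solutions the two estimators coincide.

Two sensitivity variants mirror common practice: a crude arithmetic CV
(mean over patients of s_i / ybar_i) and a log-scale CV
(sqrt(exp(sigma_w,log^2) - 1) from components fitted to log values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DataError, DomainError, EstimationError

__all__ = [
    "VarianceComponents",
    "CVEstimate",
    "fit_components_moments",
    "fit_components_reml",
    "cv_from_components",
    "cv_model",
    "cv_bootstrap",
    "cv_crude",
    "cv_log",
]


@dataclass
class VarianceComponents:
    grand_mean: float
    within_sd: float
    between_sd: float
    n_patients: int
    n_records: int
    method: str  # "moments" | "reml"
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        assert self.within_sd >= 0 and self.between_sd >= 0
        assert self.n_records >= self.n_patients >= 1


@dataclass
class CVEstimate:
    cv: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = "model"  # "model" | "crude" | "log"

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.cv + 1e-12 and self.cv <= self.ci_high + 1e-12):
            raise AssertionError(
                f"CI invariant violated: {self.ci_low} <= {self.cv} <= {self.ci_high}"
            )

    def to_dict(self) -> dict:
        return {
            "cv": self.cv,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "method": self.method,
        }


def _patient_stats(results: pd.DataFrame):
    """Per-patient (n_i, ybar_i, SS_i) with the >= 2 records precondition."""
    g = results.groupby("patient_id", sort=False)["value"]
    n_i = g.size().to_numpy(dtype=np.int64)
    if (n_i < 2).any():
        bad = g.size()
        offender = bad[bad < 2].index[0]
        raise DataError(f"patient {offender!r} has fewer than 2 records")
    ybar = g.mean().to_numpy()
    ss = (g.var(ddof=0) * n_i).to_numpy()  # within-patient sum of squares
    return n_i, ybar, ss


def fit_components_moments(results: pd.DataFrame) -> VarianceComponents:
    """Unbalanced one-way ANOVA moment estimator.

    sigma_w^2 is the pooled within-patient variance SSW / (N - k); sigma_b^2
    comes from equating the between-groups mean square to its expectation,
    truncated at zero.
    """
    n_i, ybar, ss = _patient_stats(results)
    k = len(n_i)
    N = int(n_i.sum())
    grand = float(results["value"].mean())
    ssw = float(ss.sum())
    sw2 = ssw / (N - k)
    if k > 1:
        ssb = float((n_i * (ybar - grand) ** 2).sum())
        msb = ssb / (k - 1)
        n0 = (N - float((n_i**2).sum()) / N) / (k - 1)
        sb2 = max((msb - sw2) / n0, 0.0)
    else:
        sb2 = 0.0
    return VarianceComponents(
        grand_mean=grand,
        within_sd=float(np.sqrt(sw2)),
        between_sd=float(np.sqrt(sb2)),
        n_patients=k,
        n_records=N,
        method="moments",
    )


def _profile_reml_objective(log_lam, n_i, ybar, ssw, N):
    """-2 restricted log-likelihood profiled over mu and sigma_w^2.

    With lambda = sigma_b^2/sigma_w^2 fixed, the GLS intercept and the REML
    estimate of sigma_w^2 have closed forms, leaving a smooth 1-D criterion.
    """
    lam = np.exp(log_lam)
    d = 1.0 + n_i * lam
    w = n_i / d
    mu = float((w * ybar).sum() / w.sum())
    q = ssw + float((n_i * (ybar - mu) ** 2 / d).sum())
    return (N - 1) * np.log(q) + float(np.log(d).sum()) + np.log(w.sum())


def _profile_reml_score(log_lam, n_i, ybar, ssw, N):
    """d/d(log lambda) of the profiled criterion (envelope theorem in mu)."""
    lam = np.exp(log_lam)
    d = 1.0 + n_i * lam
    w = n_i / d
    S = float(w.sum())
    mu = float((w * ybar).sum() / S)
    r2 = (ybar - mu) ** 2
    q = ssw + float((n_i * r2 / d).sum())
    dq = -float((n_i**2 * r2 / d**2).sum())
    ds = -float((n_i**2 / d**2).sum())
    return lam * ((N - 1) * dq / q + S + ds / S)


def fit_components_reml(results: pd.DataFrame, tol: float = 1e-10,
                        max_iter: int = 200) -> VarianceComponents:
    """REML estimates of (sigma_b^2, sigma_w^2), constrained non-negative.

    The criterion is minimised over log(lambda) on a wide bracket; lambda
    values indistinguishable from zero collapse to the boundary solution
    sigma_b^2 = 0 (whose profiled sigma_w^2 is SST / (N - 1)).
    """
    n_i, ybar, ss = _patient_stats(results)
    k = len(n_i)
    N = int(n_i.sum())
    ssw = float(ss.sum())
    grand = float(results["value"].mean())

    # standardize by the grand mean so the optimisation (and hence the CV)
    # is invariant under rescaling of the data
    scale = abs(grand) if grand != 0 else 1.0
    ybar = ybar / scale
    ssw = ssw / scale**2

    if ssw <= 0.0:
        # degenerate: no within-patient variation at all
        sb2 = fit_components_moments(results).between_sd ** 2
        return VarianceComponents(grand, 0.0, float(np.sqrt(sb2)), k, N, "reml")
    if k == 1:
        sw2 = ssw / (N - 1)
        return VarianceComponents(grand, float(np.sqrt(sw2)) * scale, 0.0, k, N, "reml")

    res = optimize.minimize_scalar(
        _profile_reml_objective,
        bounds=(-34.0, 34.0),
        args=(n_i, ybar, ssw, N),
        method="bounded",
        options={"xatol": tol, "maxiter": max_iter},
    )
    if not res.success:
        raise EstimationError(
            f"REML failed to converge in {max_iter} iterations "
            f"(nfev={res.nfev}, message={res.message!r})"
        )
    # polish the interior optimum on the analytic score: value-based search
    # alone is limited by objective noise near the flat minimum
    x = float(res.x)
    lo, hi = x - 0.05, x + 0.05
    try:
        slo = _profile_reml_score(lo, n_i, ybar, ssw, N)
        shi = _profile_reml_score(hi, n_i, ybar, ssw, N)
        if slo < 0 < shi:
            x = float(optimize.brentq(_profile_reml_score, lo, hi,
                                      args=(n_i, ybar, ssw, N), xtol=1e-13))
            res.x = x
            res.fun = _profile_reml_objective(x, n_i, ybar, ssw, N)
    except ValueError:
        pass
    # compare the interior optimum against the sigma_b^2 = 0 boundary
    sst = ssw + float((n_i * (ybar - _gls_mean(n_i, ybar, 0.0)) ** 2).sum())
    f_boundary = (N - 1) * np.log(sst) + np.log(float(n_i.sum()))
    if f_boundary <= res.fun or np.exp(res.x) < 1e-12:
        sw2 = sst / (N - 1)
        sb2 = 0.0
    else:
        lam = float(np.exp(res.x))
        d = 1.0 + n_i * lam
        w = n_i / d
        mu = float((w * ybar).sum() / w.sum())
        sw2 = (ssw + float((n_i * (ybar - mu) ** 2 / d).sum())) / (N - 1)
        sb2 = lam * sw2
    return VarianceComponents(
        grand_mean=grand,
        within_sd=float(np.sqrt(sw2)) * scale,
        between_sd=float(np.sqrt(sb2)) * scale,
        n_patients=k,
        n_records=N,
        method="reml",
        converged=bool(res.success),
        n_iter=int(res.nfev),
    )


def _gls_mean(n_i, ybar, lam):
    d = 1.0 + n_i * lam
    w = n_i / d
    return float((w * ybar).sum() / w.sum())


def cv_from_components(vc: VarianceComponents, level: float = 0.95) -> CVEstimate:
    """CV = sigma_w / mu with a chi-square interval on sigma_w^2.

    The interval uses N - k degrees of freedom (the within-patient residual
    dimension) and treats the grand mean as fixed; this is exact for the
    pooled-variance estimator under the model.
    """
    if vc.grand_mean <= 0:
        raise DomainError(f"grand mean must be positive, got {vc.grand_mean}")
    cv = vc.within_sd / vc.grand_mean
    df = vc.n_records - vc.n_patients
    if vc.within_sd == 0.0 or df < 1:
        return CVEstimate(cv=cv, ci_low=cv, ci_high=cv, level=level, method="model")
    alpha = 1.0 - level
    sw2 = vc.within_sd**2
    lo = np.sqrt(sw2 * df / stats.chi2.ppf(1 - alpha / 2, df)) / vc.grand_mean
    hi = np.sqrt(sw2 * df / stats.chi2.ppf(alpha / 2, df)) / vc.grand_mean
    return CVEstimate(cv=float(cv), ci_low=float(lo), ci_high=float(hi), level=level, method="model")


def cv_model(results: pd.DataFrame, method: str = "reml", level: float = 0.95,
             ci: str = "chisq", n_boot: int = 500, seed: int = 0):
    """Convenience wrapper: fit components and return (components, estimate)."""
    if method == "reml":
        vc = fit_components_reml(results)
    elif method == "moments":
        vc = fit_components_moments(results)
    else:
        raise DomainError(f"unknown method {method!r}")
    if ci == "chisq":
        est = cv_from_components(vc, level=level)
    elif ci == "bootstrap":
        est = cv_bootstrap(results, method=method, level=level, n_boot=n_boot, seed=seed)
    else:
        raise DomainError(f"unknown ci method {ci!r}")
    return vc, est


def cv_bootstrap(results: pd.DataFrame, method: str = "moments", level: float = 0.95,
                 n_boot: int = 500, seed: int = 0) -> CVEstimate:
    """Patient-level resampling percentile interval for the model CV."""
    rng = np.random.default_rng(seed)
    fit = fit_components_reml if method == "reml" else fit_components_moments
    vc = fit(results)
    point = vc.within_sd / vc.grand_mean
    ids = results["patient_id"].unique()
    groups = {pid: g for pid, g in results.groupby("patient_id", sort=False)}
    draws = np.empty(n_boot)
    for b in range(n_boot):
        sample = rng.choice(ids, size=len(ids), replace=True)
        frames = []
        for j, pid in enumerate(sample):
            g = groups[pid].copy()
            g["patient_id"] = f"b{j}"
            frames.append(g)
        boot = pd.concat(frames, ignore_index=True)
        v = fit(boot)
        draws[b] = v.within_sd / v.grand_mean
    alpha = 1.0 - level
    lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
    return CVEstimate(
        cv=float(point),
        ci_low=float(min(lo, point)),
        ci_high=float(max(hi, point)),
        level=level,
        method="model",
    )


def cv_crude(results: pd.DataFrame, level: float = 0.95) -> CVEstimate:
    """Crude arithmetic CV: each patient's s_i / ybar_i, averaged by the mean.

    The interval is a normal approximation over the patient-level CVs.
    """
    g = results.groupby("patient_id", sort=False)["value"]
    n_i = g.size()
    if (n_i < 2).any():
        raise DataError(f"patient {n_i[n_i < 2].index[0]!r} has fewer than 2 records")
    ybar = g.mean()
    if (ybar <= 0).any():
        raise DomainError(f"patient {ybar[ybar <= 0].index[0]!r} has non-positive mean")
    pcv = (g.std(ddof=1) / ybar).to_numpy()
    k = len(pcv)
    point = float(pcv.mean())
    if k > 1:
        se = float(pcv.std(ddof=1) / np.sqrt(k))
        z = stats.norm.ppf(0.5 + level / 2)
        lo, hi = max(point - z * se, 0.0), point + z * se
    else:
        lo = hi = point
    return CVEstimate(cv=point, ci_low=lo, ci_high=hi, level=level, method="crude")


def cv_log(results: pd.DataFrame, level: float = 0.95, method: str = "moments") -> CVEstimate:
    """CV from components fitted on the natural-log scale.

    If sigma_L is the within-patient SD of log values, the implied CV on the
    raw scale is sqrt(exp(sigma_L^2) - 1); for small sigma_L this approaches
    sigma_L itself.
    """
    if (results["value"] <= 0).any():
        bad = results.index[results["value"] <= 0][0]
        raise DomainError(f"non-positive value at row {bad}; log CV undefined")
    logged = results.assign(value=np.log(results["value"]))
    fit = fit_components_reml if method == "reml" else fit_components_moments
    vc = fit(logged)
    df = vc.n_records - vc.n_patients
    s2 = vc.within_sd**2
    point = float(np.sqrt(np.expm1(s2)))
    if vc.within_sd == 0.0 or df < 1:
        return CVEstimate(cv=point, ci_low=point, ci_high=point, level=level, method="log")
    alpha = 1.0 - level
    s2_lo = s2 * df / stats.chi2.ppf(1 - alpha / 2, df)
    s2_hi = s2 * df / stats.chi2.ppf(alpha / 2, df)
    return CVEstimate(
        cv=point,
        ci_low=float(np.sqrt(np.expm1(s2_lo))),
        ci_high=float(np.sqrt(np.expm1(s2_hi))),
        level=level,
        method="log",
    )
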