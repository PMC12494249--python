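import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_results
from hbvar.exceptions import DataError, DomainError
from hbvar.synthetic_cohort import SimConfig, StratumSpec, VisitCountLaw, generate_cohort
from hbvar.variance_cv import (
    cv_bootstrap,
    cv_crude,
    cv_from_components,
    cv_log,
    cv_model,
    fit_components_moments,
    fit_components_reml,
)


def simulate_unbalanced(seed, k=60, mu=55.0, between_sd=9.0, within_sd=6.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(k):
        n = int(rng.integers(2, 9))
        m = rng.normal(mu, between_sd)
        for j in range(n):
            rows.append((f"P{i:03d}", pd.Timestamp("2015-01-01") + pd.Timedelta(days=40 * j), rng.normal(m, within_sd)))
    return make_results(rows)


class TestMoments:
    def test_toy_hand_anova(self, toy_cohort):
        vc = fit_components_moments(toy_cohort)
        assert vc.within_sd**2 == pytest.approx(8.0, rel=1e-12)
        assert vc.grand_mean == 52.0
        assert cv_from_components(vc).cv == pytest.approx(np.sqrt(8) / 52, rel=1e-12)

    def test_constant_patients_zero_within(self):
        r = make_results([(p, f"2015-0{m}-01", 50.0 + i) for i, p in enumerate("AB") for m, _ in enumerate(range(3), 1)])
        vc = fit_components_moments(r)
        assert vc.within_sd == 0.0

    def test_single_patient_degenerate(self):
        r = make_results([("A", f"2015-0{m}-01", v) for m, v in enumerate([48, 50, 52], 1)])
        vc = fit_components_moments(r)
        assert vc.within_sd == pytest.approx(np.std([48, 50, 52], ddof=1))
        assert vc.between_sd == 0.0

    def test_patient_with_single_record_rejected(self):
        r = make_results([("A", "2015-01-01", 50), ("A", "2015-02-01", 52), ("B", "2015-01-01", 55)])
        with pytest.raises(DataError, match="B"):
            fit_components_moments(r)


class TestREML:
    def test_matches_moments_on_balanced_interior(self, toy_cohort):
        vm = fit_components_moments(toy_cohort)
        vr = fit_components_reml(toy_cohort)
        assert vr.within_sd**2 == pytest.approx(vm.within_sd**2, rel=1e-6)
        assert vr.between_sd**2 == pytest.approx(vm.between_sd**2, rel=1e-6)

    def test_matches_statsmodels_mixedlm_on_unbalanced_data(self):
        sm = pytest.importorskip("statsmodels.api")
        r = simulate_unbalanced(seed=42)
        vr = fit_components_reml(r)
        fit = sm.MixedLM(r["value"], np.ones((len(r), 1)), groups=r["patient_id"]).fit(reml=True)
        assert vr.within_sd**2 == pytest.approx(float(fit.scale), rel=1e-4)
        assert vr.between_sd**2 == pytest.approx(float(fit.cov_re.iloc[0, 0]), rel=1e-3)

    def test_zero_within_noise_gives_zero_sigma_w(self):
        cfg = SimConfig(seed=0, n_patients=40, strata=[StratumSpec("a", 1.0, 50.0, 5.0, 0.0)],
                        visit_count_law=VisitCountLaw(name="fixed", n=5))
        cohort, _ = generate_cohort(cfg)
        vr = fit_components_reml(cohort.results)
        assert vr.within_sd == 0.0
        assert vr.between_sd > 0

    def test_between_variance_truncated_at_zero(self):
        # patient means closer together than within-noise allows by chance
        rng = np.random.default_rng(1)
        rows = [(f"P{i}", pd.Timestamp("2015-01-01") + pd.Timedelta(days=30 * j), rng.normal(50, 10))
                for i in range(20) for j in range(4)]
        vr = fit_components_reml(make_results(rows))
        assert vr.between_sd >= 0.0

    def test_parameter_recovery_on_unbalanced_synthetic_cohort(self):
        cfg = SimConfig(seed=8, n_patients=2000,
                        strata=[StratumSpec("a", 1.0, 52.31, 8.0, 0.20)],
                        visit_count_law=VisitCountLaw(min_visits=2))
        cohort, _ = generate_cohort(cfg)
        vr = fit_components_reml(cohort.results)
        assert vr.within_sd / vr.grand_mean == pytest.approx(0.20, abs=0.01)


class TestCVFromComponents:
    def test_ci_ordering_invariant(self, toy_cohort):
        est = cv_from_components(fit_components_moments(toy_cohort))
        assert 0 <= est.ci_low <= est.cv <= est.ci_high

    def test_zero_within_sd_degenerate_interval(self):
        r = make_results([(p, f"2015-0{m}-01", 50.0) for p in "AB" for m in range(1, 4)])
        est = cv_from_components(fit_components_moments(r))
        assert est.cv == 0.0 and est.ci_low == 0.0

    def test_nonpositive_mean_rejected(self, toy_cohort):
        vc = fit_components_moments(toy_cohort.assign(value=toy_cohort["value"] - 100))
        with pytest.raises(DomainError):
            cv_from_components(vc)

    def test_ci_width_shrinks_with_information(self):
        widths = []
        for n in (100, 1000, 10000):
            rng = np.random.default_rng(n)
            rows = [(f"P{i}", pd.Timestamp("2015-01-01") + pd.Timedelta(days=30 * j), rng.normal(52, 10))
                    for i in range(n) for j in range(4)]
            est = cv_from_components(fit_components_moments(make_results(rows)))
            widths.append(est.ci_high - est.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_bootstrap_interval_brackets_point(self):
        r = simulate_unbalanced(seed=5, k=40)
        est = cv_bootstrap(r, n_boot=60, seed=1)
        assert est.ci_low <= est.cv <= est.ci_high
        assert est.ci_high > est.ci_low


class TestCrude:
    def test_toy_hand_computation(self, toy_cohort):
        # per-patient CVs: sqrt(8)/42, sqrt(8)/52, sqrt(8)/62
        expected = np.mean([np.sqrt(8) / m for m in (42, 52, 62)])
        assert cv_crude(toy_cohort).cv == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0558, abs=5e-4)

    def test_constant_patients_zero(self):
        r = make_results([(p, f"2015-0{m}-01", 50.0) for p in "AB" for m in range(1, 4)])
        assert cv_crude(r).cv == 0.0

    def test_single_patient_equals_own_ratio(self):
        r = make_results([("A", f"2015-0{m}-01", v) for m, v in enumerate([48, 50, 52], 1)])
        assert cv_crude(r).cv == pytest.approx(np.std([48, 50, 52], ddof=1) / 50)


class TestLogCV:
    def test_zero_noise_gives_zero(self):
        r = make_results([(p, f"2015-0{m}-01", 50.0) for p in "AB" for m in range(1, 4)])
        assert cv_log(r).cv == 0.0

    def test_lognormal_within_noise_recovered(self):
        rng = np.random.default_rng(3)
        cv_true = 0.10
        sigma = np.sqrt(np.log1p(cv_true**2))
        rows = []
        for i in range(1500):
            mu = rng.normal(52, 6)
            for j in range(8):
                rows.append((f"P{i}", pd.Timestamp("2015-01-01") + pd.Timedelta(days=30 * j),
                             mu * np.exp(rng.normal(0, sigma))))
        assert cv_log(make_results(rows)).cv == pytest.approx(cv_true, abs=0.01)

    def test_small_cv_taylor_limit(self):
        rng = np.random.default_rng(4)
        sigma = np.sqrt(np.log1p(0.02**2))
        rows = [(f"P{i}", pd.Timestamp("2015-01-01") + pd.Timedelta(days=30 * j),
                 50 * np.exp(rng.normal(0, sigma))) for i in range(400) for j in range(6)]
        r = make_results(rows)
        est = cv_log(r)
        vc = fit_components_moments(r.assign(value=np.log(r["value"])))
        assert est.cv == pytest.approx(vc.within_sd, abs=1e-3)

    def test_nonpositive_values_rejected(self, toy_cohort):
        with pytest.raises(DomainError):
            cv_log(toy_cohort.assign(value=toy_cohort["value"] - 45))


class TestScaleInvariance:
    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_cv_variants_invariant_under_rescaling(self, scale):
        toy = make_results(
            [("A", "2015-01-01", 40), ("A", "2015-02-01", 44),
             ("B", "2015-01-01", 50), ("B", "2015-02-01", 54),
             ("C", "2015-01-01", 60), ("C", "2015-02-01", 64)]
        )
        scaled = toy.assign(value=toy["value"] * scale)
        base_m = cv_from_components(fit_components_moments(toy)).cv
        assert cv_from_components(fit_components_moments(scaled)).cv == pytest.approx(base_m, rel=1e-12)
        assert cv_crude(scaled).cv == pytest.approx(cv_crude(toy).cv, rel=1e-12)

    def test_reml_cv_invariant_under_rescaling(self):
        r = simulate_unbalanced(seed=10, k=30)
        base = fit_components_reml(r)
        for a in (0.01, 3.7, 250.0):
            vr = fit_components_reml(r.assign(value=r["value"] * a))
            assert vr.within_sd / vr.grand_mean == pytest.approx(base.within_sd / base.grand_mean, rel=1e-9)

    def test_log_cv_invariant_under_rescaling(self):
        r = simulate_unbalanced(seed=11, k=30, mu=60, within_sd=4.0)
        base = cv_log(r).cv
        assert cv_log(r.assign(value=r["value"] * 7.3)).cv == pytest.approx(base, rel=1e-9)


def test_cv_model_wrapper_dispatch(toy_cohort):
    vc, est = cv_model(toy_cohort, method="moments")
    assert vc.method == "moments" and est.method == "model"
    with pytest.raises(DomainError):
        cv_model(toy_cohort, method="nope")
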