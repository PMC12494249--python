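import numpy as np
import pandas as pd
import pytest

from conftest import make_results
from hbvar.exceptions import SpecificationError
from hbvar.subgroups import (
    SubgroupSpec,
    cross_classified_cv,
    derive_features,
    results_table,
    stratified_cv,
    stratified_cv_by_status,
)
from hbvar.synthetic_cohort import SimConfig, StratumSpec, VisitCountLaw, generate_cohort
from hbvar.variance_cv import cv_from_components, fit_components_moments


@pytest.fixture(scope="module")
def two_stratum_cohort():
    cfg = SimConfig(
        seed=12,
        n_patients=4000,
        strata=[
            StratumSpec("no_dm", 0.5, 38.24, 3.5, 0.09),
            StratumSpec("t2dm", 0.5, 58.70, 8.0, 0.19),
        ],
        visit_count_law=VisitCountLaw(name="fixed", n=10),
    )
    cohort, _ = generate_cohort(cfg)
    return cohort


class TestDeriveFeatures:
    def test_median_gap_and_central_values(self):
        r = make_results([("A", "2015-01-01", 40), ("A", "2015-04-11", 50), ("A", "2015-07-20", 60)])
        f = derive_features(r)
        row = f.set_index("patient_id").loc["A"]
        assert row["median_gap_days"] == 100
        assert row["mean_hba1c"] == 50 and row["median_hba1c"] == 50
        assert row["n_measurements"] == 3

    @pytest.mark.parametrize(
        "bmi,band",
        [(17.0, "<18.5"), (18.5, "18.5 to <25"), (25.0, "25 to <30"),
         (30.0, "30 to <35"), (35.0, ">35"), (np.nan, "missing")],
    )
    def test_bmi_bands(self, bmi, band):
        r = make_results([("A", "2015-01-01", 50), ("A", "2015-02-01", 52)])
        cov = pd.DataFrame({"patient_id": ["A"], "bmi": [bmi], "age": [50]})
        f = derive_features(r, cov)
        assert f["bmi_band"].iloc[0] == band

    @pytest.mark.parametrize("age,band", [(9, "<=10"), (10, "<=10"), (11, "11-20"), (70, "61-70"), (101, ">100")])
    def test_age_bands(self, age, band):
        r = make_results([("A", "2015-01-01", 50), ("A", "2015-02-01", 52)])
        cov = pd.DataFrame({"patient_id": ["A"], "bmi": [25.0], "age": [age]})
        f = derive_features(r, cov)
        assert f["age_band"].iloc[0] == band


class TestStratifiedCV:
    def test_single_stratum_equals_whole_cohort(self, two_stratum_cohort):
        res = two_stratum_cohort.results
        feats = derive_features(res, two_stratum_cohort.covariates)
        out = stratified_cv(res, feats, SubgroupSpec("diabetic_status", categories=None, min_group_size=2),
                            method="moments")
        whole = cv_from_components(fit_components_moments(res)).cv
        # two strata; pooled CV must exceed the low stratum and the strata
        # recover their generating CVs
        by = {r.stratum: r for r in out}
        assert by["no_dm"].estimate.cv == pytest.approx(0.09, abs=0.015)
        assert by["t2dm"].estimate.cv == pytest.approx(0.19, abs=0.015)
        assert whole > by["no_dm"].estimate.cv

    def test_partition_counts_sum_to_cohort(self, two_stratum_cohort):
        res = two_stratum_cohort.results
        feats = derive_features(res, two_stratum_cohort.covariates)
        out = stratified_cv(res, feats, SubgroupSpec("sex"), method="moments")
        assert sum(r.n_patients for r in out) == res["patient_id"].nunique()
        assert sum(r.n_records for r in out) == len(res)

    def test_floor_suppression(self):
        cfg = SimConfig(seed=3, n_patients=99, strata=[StratumSpec("a", 1.0, 52.0, 5.0, 0.15)],
                        visit_count_law=VisitCountLaw(name="fixed", n=5))
        cohort, _ = generate_cohort(cfg)
        feats = derive_features(cohort.results, cohort.covariates)
        out = stratified_cv(cohort.results, feats, SubgroupSpec("diabetic_status"))
        assert len(out) == 1 and out[0].suppressed and out[0].estimate is None
        assert out[0].n_patients == 99

    def test_unknown_variable_raises(self, two_stratum_cohort):
        feats = derive_features(two_stratum_cohort.results, two_stratum_cohort.covariates)
        with pytest.raises(SpecificationError, match="nonexistent"):
            stratified_cv(two_stratum_cohort.results, feats, SubgroupSpec("nonexistent"))

    def test_numeric_binning_with_missing_category(self, two_stratum_cohort):
        res = two_stratum_cohort.results
        feats = derive_features(res, two_stratum_cohort.covariates)
        spec = SubgroupSpec("mean_hba1c", bin_edges=[20, 45, 60, 200], min_group_size=50)
        out = stratified_cv(res, feats, spec, method="moments")
        assert sum(r.n_patients for r in out) == res["patient_id"].nunique()
        assert all(r.stratum.startswith("[") or r.stratum == "missing" for r in out)


class TestStatusChange:
    def test_segments_of_at_least_four_results_contribute(self):
        recs = ([("A", f"2015-{m:02d}-01", 40.0 + m % 2) for m in range(1, 6)]      # 5 no_dm
                + [("A", f"2016-{m:02d}-01", 58.0 + m % 2) for m in range(1, 7)]    # 6 t2dm
                + [("B", f"2015-{m:02d}-01", 50.0 + m % 2) for m in range(1, 4)])   # 3 only -> excluded
        r = make_results(recs)
        r["diabetic_status"] = ["no_dm"] * 5 + ["t2dm"] * 6 + ["no_dm"] * 3
        out = stratified_cv_by_status(r, min_group_size=1, method="moments")
        by = {o.stratum: o for o in out}
        assert by["no_dm"].n_records == 5   # only A's first run; B's 3-run excluded
        assert by["t2dm"].n_records == 6

    def test_short_runs_everywhere_excludes_patient(self):
        r = make_results([("A", f"2015-{m:02d}-01", 50.0) for m in range(1, 7)])
        r["diabetic_status"] = ["no_dm", "no_dm", "t2dm", "t2dm", "no_dm", "no_dm"]
        out = stratified_cv_by_status(r, min_group_size=1)
        assert out == []


class TestCrossClassified:
    def test_sex_by_status_grid_conserves_counts(self, two_stratum_cohort):
        res = two_stratum_cohort.results
        feats = derive_features(res, two_stratum_cohort.covariates)
        grid = cross_classified_cv(res, feats, [SubgroupSpec("sex"), SubgroupSpec("diabetic_status")],
                                   method="moments")
        assert len(grid) == 4  # 2 sexes x 2 strata in this cohort
        assert grid["n_patients"].sum() == res["patient_id"].nunique()

    def test_cell_membership_matches_brute_force_filter(self, two_stratum_cohort):
        res = two_stratum_cohort.results
        cov = two_stratum_cohort.covariates
        feats = derive_features(res, cov)
        grid = cross_classified_cv(res, feats, [SubgroupSpec("sex"), SubgroupSpec("diabetic_status")],
                                   method="moments")
        pick = cov[(cov["sex"] == "male") & (cov["diabetic_status"] == "t2dm")]["patient_id"]
        cell = grid[(grid["sex"] == "male") & (grid["diabetic_status"] == "t2dm")].iloc[0]
        assert cell["n_patients"] == pick.nunique()
        direct = cv_from_components(
            fit_components_moments(res[res["patient_id"].isin(pick)])
        ).cv
        assert cell["cv"] == pytest.approx(direct, rel=1e-12)

    def test_degenerate_single_cell_equals_whole_cohort(self, two_stratum_cohort):
        res = two_stratum_cohort.results
        feats = derive_features(res, two_stratum_cohort.covariates).assign(everyone="all")
        grid = cross_classified_cv(res, feats, [SubgroupSpec("everyone")], method="moments")
        whole = cv_from_components(fit_components_moments(res)).cv
        assert len(grid) == 1
        assert grid["cv"].iloc[0] == pytest.approx(whole, rel=1e-12)

    def test_too_many_specs_rejected(self, two_stratum_cohort):
        feats = derive_features(two_stratum_cohort.results, two_stratum_cohort.covariates)
        with pytest.raises(SpecificationError):
            cross_classified_cv(two_stratum_cohort.results, feats, [SubgroupSpec("sex")] * 5)


def test_results_table_flattens(two_stratum_cohort):
    res = two_stratum_cohort.results
    feats = derive_features(res, two_stratum_cohort.covariates)
    table = results_table(stratified_cv(res, feats, SubgroupSpec("diabetic_status"), method="moments"))
    assert set(table.columns) >= {"variable", "stratum", "n_patients", "cv", "suppressed"}
    assert len(table) == 2
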