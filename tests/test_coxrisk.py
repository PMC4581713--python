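import numpy as np
import pandas as pd
import pytest

from mammorisk.coxrisk import (
    MODEL_SPECS,
    CoxRiskModel,
    FitError,
    breslow_cumulative_hazard,
    encode_design,
)
from mammorisk.genotypes import default_panel, simulate_genotype_dataset
from mammorisk.schema import SchemaError, default_schema

from conftest import make_exponential_cohort


def _reference_row():
    schema = default_schema()
    return pd.DataFrame({v.name: [v.reference] for v in schema.variables})


class TestEncodeDesign:
    def test_all_reference_subject_is_zero_row(self):
        design = encode_design(_reference_row(), MODEL_SPECS["gail_bmi_density"])
        assert (design.to_numpy() == 0).all()

    def test_single_nonreference_level_sets_one_dummy(self):
        row = _reference_row()
        row.loc[0, "bmi"] = ">=28"
        design = encode_design(row, MODEL_SPECS["gail_bmi"])
        assert design.to_numpy().sum() == 1.0
        assert design.loc[0, "bmi[>=28]"] == 1.0

    def test_dummy_counts_per_model(self, small_cohort):
        grs = np.zeros(len(small_cohort))
        assert encode_design(small_cohort, MODEL_SPECS["gail_bmi"]).shape[1] == 15
        assert (
            encode_design(small_cohort, MODEL_SPECS["gail_bmi_density"]).shape[1] == 20
        )
        d3 = encode_design(small_cohort, MODEL_SPECS["gail_bmi_density_grs"], grs=grs)
        assert d3.shape[1] == 21 and "grs" in d3.columns

    def test_unseen_level_raises(self, small_cohort):
        bad = small_cohort.copy()
        bad.loc[bad.index[0], "ethnicity"] = "Martian"
        with pytest.raises(SchemaError):
            encode_design(bad, MODEL_SPECS["gail_bmi"])

    def test_grs_required_when_specified(self, small_cohort):
        with pytest.raises(SchemaError):
            encode_design(small_cohort, MODEL_SPECS["gail_bmi_density_grs"])


def _two_group_cohort(n=5000, hr=2.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=n)
    df = make_exponential_cohort(
        n, rate_per_day=2e-4, censor_day=4000, seed=seed + 1, lp=np.log(hr) * x
    )
    df["exposed"] = np.where(x == 1, "yes", "no")
    return df


def _fit_simple(df, extra_cols=("exposed",)):
    from mammorisk.schema import CategoricalVariable, CovariateSchema
    from mammorisk.coxrisk import ModelSpec

    schema = CovariateSchema(
        tuple(
            CategoricalVariable(c, ("no", "yes"), (0.5, 0.5)) for c in extra_cols
        )
    )
    spec = ModelSpec("simple", tuple(extra_cols))
    return CoxRiskModel(df, spec, schema=schema).fit()


class TestPartialLikelihoodFit:
    def test_recovers_true_hazard_ratio(self):
        df = _two_group_cohort()
        res = _fit_simple(df)
        beta = res.params["exposed[yes]"]
        se = res.standard_errors["exposed[yes]"]
        assert abs(beta - np.log(2.0)) < 3 * se

    def test_null_covariate_recovers_zero(self):
        df = _two_group_cohort(hr=1.0, seed=5)
        res = _fit_simple(df)
        assert abs(res.params["exposed[yes]"]) < 3 * res.standard_errors["exposed[yes]"]

    def test_row_permutation_invariance(self):
        df = _two_group_cohort(n=2000, seed=7)
        res_a = _fit_simple(df)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        res_b = _fit_simple(shuffled)
        assert abs(res_a.params.iloc[0] - res_b.params.iloc[0]) < 1e-8

    def test_too_few_events_rejected(self):
        df = _two_group_cohort(n=50)
        df["event"] = 0
        with pytest.raises(FitError):
            _fit_simple(df)

    def test_constant_column_rejected_upstream(self):
        df = _two_group_cohort(n=200, seed=9)
        df["exposed"] = "yes"
        with pytest.raises(FitError, match="constant"):
            _fit_simple(df)

    def test_full_specification_on_synthetic_cohort(self, full_cohort):
        panel = default_panel()
        grs = simulate_genotype_dataset(
            panel, full_cohort["event"].to_numpy(dtype=int), seed=21
        ).grs
        res = CoxRiskModel(full_cohort, "gail_bmi_density_grs", grs=grs).fit()
        tab = res.summary_frame()
        assert len(tab) == 21
        assert np.isfinite(tab["coef"]).all()
        # internal consistency: HR column is exp(coef)
        np.testing.assert_allclose(
            tab["hazard_ratio"], np.exp(tab["coef"]), rtol=1e-10
        )
        assert "grs" in res.summary()


class TestBaselineHazard:
    def test_nelson_aalen_consistency_for_exponential_data(self):
        # single profile, rate lambda: H0(10y) should approach 10*lambda
        lam_year = 0.03
        df = make_exponential_cohort(
            10_000, rate_per_day=lam_year / 365.25, censor_day=6000, seed=11
        )
        times, h0 = breslow_cumulative_hazard(
            np.zeros(len(df)), df["time"].to_numpy(), df["event"].to_numpy()
        )
        idx = np.searchsorted(times, 3652, side="right") - 1
        assert abs(h0[idx] - 10 * lam_year) / (10 * lam_year) < 0.05

    def test_time_rescaling_halves_cumulative_hazard(self):
        # H_scaled(t) = H_orig(t/2) when all follow-up times double
        df = make_exponential_cohort(4000, rate_per_day=5e-4, censor_day=3000, seed=12)
        t = df["time"].to_numpy()
        e = df["event"].to_numpy()
        t_orig, h_orig = breslow_cumulative_hazard(np.zeros(len(df)), t, e)
        t_scaled, h_scaled = breslow_cumulative_hazard(np.zeros(len(df)), 2 * t, e)
        i = np.searchsorted(t_scaled, 1000, side="right") - 1
        j = np.searchsorted(t_orig, 500, side="right") - 1
        assert np.isclose(h_scaled[i], h_orig[j], rtol=1e-12)

    def test_reference_profile_reduction(self, small_cohort):
        # categorical-only model: exp(beta'x_ref) = 1, so H0 = -log S^NA
        res = CoxRiskModel(small_cohort, "gail_bmi").fit()
        lp = res.linear_predictor
        times, h0 = breslow_cumulative_hazard(
            lp, small_cohort["time"].to_numpy(), small_cohort["event"].to_numpy()
        )
        idx = np.searchsorted(times, 3652, side="right") - 1
        assert np.isclose(res.baseline_cumhaz_10y, h0[idx], rtol=1e-12)

    def test_no_events_before_horizon_gives_zero(self):
        df = pd.DataFrame(
            {
                "time": [4000.0, 5000.0, 6000.0, 7000.0] * 30,
                "event": [0, 1, 0, 1] * 30,
                "exposed": ["no", "yes"] * 60,
            }
        )
        res = _fit_simple(df)
        assert res.baseline_cumhaz_10y == 0.0
        assert (res.predict_risk_10y() == 0.0).all()


class TestAbsoluteRisk:
    def test_baseline_closed_form(self):
        assert np.isclose(1 - np.exp(-0.0282), 0.0278, atol=5e-5)

    def test_risks_bounded_and_monotone_in_linear_predictor(self, small_cohort):
        res = CoxRiskModel(small_cohort, "gail_bmi_density").fit()
        risks = res.predict_risk_10y()
        assert np.all((risks >= 0) & (risks <= 1))
        order = np.argsort(res.linear_predictor)
        assert np.all(np.diff(risks[order]) >= 0)

    def test_risk_increases_with_grs(self, small_cohort):
        grs = np.linspace(3, 7, len(small_cohort))
        res = CoxRiskModel(small_cohort, "gail_bmi_density_grs", grs=grs).fit()
        row = small_cohort.iloc[[0]]
        risks = [
            res.predict_risk_10y(row, grs=np.array([g])).item() for g in (3.5, 4.5, 5.5)
        ]
        assert risks[0] < risks[1] < risks[2]

    def test_mean_risk_tracks_cumulative_incidence(self, full_cohort):
        # calibration-in-the-large under the reference-profile baseline
        res = CoxRiskModel(full_cohort, "gail_bmi_density").fit()
        mean_risk = res.predict_risk_10y().mean()
        incidence = full_cohort["label_10y"].mean()
        assert abs(mean_risk - incidence) / incidence < 0.2


class TestSchoenfeldCheck:
    def test_type_one_error_near_nominal_under_ph(self):
        rejections = 0
        n_sim = 200
        for s in range(n_sim):
            df = _two_group_cohort(n=250, seed=100 + s)
            res = _fit_simple(df)
            p = res.check_proportional_hazards()["p"].iloc[0]
            rejections += p < 0.05
        assert 0.02 <= rejections / n_sim <= 0.08

    def test_detects_time_varying_effect(self):
        # effect reverses sign at the median event time: strong violation
        hits = 0
        n_sim = 10
        for s in range(n_sim):
            rng = np.random.default_rng(300 + s)
            n = 5000
            x = rng.integers(0, 2, size=n)
            early = make_exponential_cohort(
                n, 3e-4, 1500, seed=400 + s, lp=np.log(3.0) * x
            )
            late = make_exponential_cohort(
                n, 3e-4, 2500, seed=500 + s, lp=-np.log(3.0) * x
            )
            cens = early["event"] == 0
            time = np.where(cens, 1500 + late["time"], early["time"])
            event = np.where(cens, late["event"], 1)
            df = pd.DataFrame(
                {
                    "time": time,
                    "event": event,
                    "exposed": np.where(x == 1, "yes", "no"),
                }
            )
            res = _fit_simple(df)
            hits += res.check_proportional_hazards()["p"].iloc[0] < 0.05
        assert hits / n_sim > 0.8
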