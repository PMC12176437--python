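"""Prevalence-ratio regression, screening, and backward elimination."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import guia_adherence.association as assoc
from guia_adherence.survey import SurveyDesign, weighted_proportion


def two_group_data(n=400, p_ref=0.10, pr=2.0, seed=0, weights="random"):
    """Binary covariate 'area', outcome drawn at p_ref / p_ref*pr."""
    rng = np.random.default_rng(seed)
    area = rng.choice(["urban", "rural"], n, p=[0.6, 0.4])
    p = np.where(area == "rural", p_ref * pr, p_ref)
    y = (rng.random(n) < p).astype(float)
    w = rng.uniform(0.5, 4.0, n) if weights == "random" else np.ones(n)
    n_psu = 40
    psu = np.array([f"p{i % n_psu}" for i in range(n)])
    strata = np.where(pd.Series(psu).str.slice(1).astype(int) < n_psu // 2, "s1", "s2")
    data = pd.DataFrame(
        {
            "greater_adherence": pd.array(y.astype(int), dtype="Int64"),
            "area": pd.Categorical(area, categories=["urban", "rural"]),
            "sex": pd.Categorical(
                rng.choice(["male", "female"], n), categories=["male", "female"]
            ),
            "stratum": strata,
            "psu": psu,
            "weight": w,
        }
    )
    return data, SurveyDesign.from_frame(data)


def spec_for(*covariates, **kwargs):
    return assoc.RegressionSpec(covariates=tuple(covariates), **kwargs)


class TestOneCovariateIdentity:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_bivariate_pr_equals_weighted_prevalence_ratio(self, seed):
        data, design = two_group_data(seed=seed)
        fit = assoc.fit_pr_model(data, design, spec_for("area"), stage="bivariate")
        y = data["greater_adherence"].to_numpy(dtype=float)
        exposed = (data["area"] == "rural").to_numpy()
        direct = weighted_proportion(y, design, exposed) / weighted_proportion(
            y, design, ~exposed
        )
        assert abs(fit.estimate("area", "rural").pr - direct) < 1e-8


class TestModelBehavior:
    def test_unweighted_limit_matches_plain_poisson_fit(self):
        data, design = two_group_data(weights="equal", seed=3)
        fit = assoc.fit_pr_model(data, design, spec_for("area", "sex"))
        X = np.column_stack(
            [
                np.ones(len(data)),
                (data["area"] == "rural").to_numpy(float),
                (data["sex"] == "female").to_numpy(float),
            ]
        )
        oracle = sm.GLM(
            data["greater_adherence"].to_numpy(float), X, family=sm.families.Poisson()
        ).fit()
        assert np.allclose(fit.params, oracle.params, atol=1e-7)

    def test_pr_invariant_to_weight_rescaling(self):
        data, design = two_group_data(seed=4)
        scaled = data.copy()
        scaled["weight"] = scaled["weight"] * 91.7
        fit1 = assoc.fit_pr_model(data, design, spec_for("area"))
        fit2 = assoc.fit_pr_model(
            scaled, SurveyDesign.from_frame(scaled), spec_for("area")
        )
        e1, e2 = fit1.estimate("area", "rural"), fit2.estimate("area", "rural")
        assert abs(e1.pr - e2.pr) < 1e-9
        assert abs(e1.ci_low - e2.ci_low) < 1e-6

    def test_null_covariate_estimate_is_near_one(self):
        data, design = two_group_data(n=2000, pr=1.0, seed=5)
        fit = assoc.fit_pr_model(data, design, spec_for("area"))
        e = fit.estimate("area", "rural")
        se_log = (np.log(e.ci_high) - np.log(e.ci_low)) / (2 * 1.96)
        assert abs(np.log(e.pr)) < 3 * se_log

    def test_reference_category_reports_pr_one_without_ci(self):
        data, design = two_group_data(seed=6)
        fit = assoc.fit_pr_model(data, design, spec_for("area"))
        ref = fit.estimate("area", "urban")
        assert ref.reference and ref.pr == 1.0 and np.isnan(ref.ci_low)

    def test_constant_outcome_is_an_error(self):
        data, design = two_group_data(seed=7)
        data["greater_adherence"] = pd.array([1] * len(data), dtype="Int64")
        with pytest.raises(ValueError, match="constant"):
            assoc.fit_pr_model(data, design, spec_for("area"))

    def test_missing_covariate_rows_are_dropped_per_analysis(self):
        data, design = two_group_data(seed=8)
        data.loc[data.index[:50], "sex"] = None
        fit = assoc.fit_pr_model(data, design, spec_for("area", "sex"))
        assert fit.n_obs == len(data) - 50


class TestScreen:
    def test_strong_effect_is_included_and_null_rate_controlled(self):
        data, design = two_group_data(n=4000, pr=3.0, seed=9)
        spec = spec_for("area", "sex")
        screen = assoc.bivariate_screen(data, design, spec)
        assert "area" in screen.included
        assert screen.p_values["area"] < 0.001

    def test_permuted_labels_usually_screened_out(self):
        # single rep sanity check; the 20% type-I rate is measured in the
        # acceptance suite over 1,000 permutations
        data, design = two_group_data(n=4000, pr=3.0, seed=10)
        rng = np.random.default_rng(0)
        data["area"] = pd.Categorical(
            rng.permutation(data["area"].to_numpy()), categories=["urban", "rural"]
        )
        screen = assoc.bivariate_screen(data, design, spec_for("area"))
        assert screen.p_values["area"] > 0.001


class TestBackwardElimination:
    def test_effect_retained_null_dropped(self):
        data, design = two_group_data(n=6000, pr=2.5, seed=11)
        spec = spec_for("area", "sex")
        fit, trace = assoc.backward_eliminate(data, design, spec, ["area", "sex"])
        assert trace.final_variables == ("area",)
        assert trace.steps[0].removed == "sex"

    def test_strict_alpha_boundary(self):
        data, design = two_group_data(n=800, pr=1.6, seed=12)
        base = assoc.fit_pr_model(data, design, spec_for("area"))
        p_obs = base.tests["area"].p_value
        # alpha just above the observed p: variable retained (strict <)
        spec_hi = spec_for("area", retain_alpha=min(0.999, p_obs + 1e-6))
        fit, trace = assoc.backward_eliminate(data, design, spec_hi, ["area"])
        assert trace.final_variables == ("area",)
        # alpha at/below the observed p: removed
        spec_lo = spec_for("area", retain_alpha=max(1e-6, p_obs - 1e-6))
        fit, trace = assoc.backward_eliminate(data, design, spec_lo, ["area"])
        assert trace.final_variables == ()
        assert fit is None

    def test_all_null_model_can_end_empty(self):
        data, design = two_group_data(n=3000, pr=1.0, seed=13)
        fit, trace = assoc.backward_eliminate(
            data, design, spec_for("area", "sex"), ["area", "sex"]
        )
        assert set(trace.final_variables) | {s.removed for s in trace.steps} == {
            "area",
            "sex",
        }

    def test_selection_is_deterministic(self):
        data, design = two_group_data(n=3000, pr=1.8, seed=14)
        spec = spec_for("area", "sex")
        runs = [
            assoc.backward_eliminate(data, design, spec, ["area", "sex"])[1].to_records()
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_estimation_sample_fixed_during_elimination(self):
        data, design = two_group_data(n=4000, pr=2.5, seed=15)
        data.loc[data.index[:300], "sex"] = None
        fit, trace = assoc.backward_eliminate(
            data, design, spec_for("area", "sex"), ["area", "sex"]
        )
        # even after sex is dropped, the fixed complete-case sample excludes
        # the 300 records with missing sex
        assert fit is not None and fit.n_obs == len(data) - 300


class TestReport:
    def test_report_structure(self, small_survey):
        data, design = small_survey["data"], small_survey["design"]
        spec = spec_for("area", "sex", "laxatives", single_psu="certainty")
        screen = assoc.bivariate_screen(data, design, spec)
        fit, trace = assoc.backward_eliminate(data, design, spec, screen.included)
        report = assoc.association_report(data, design, spec, screen, fit)
        assert set(report["variable"]) == {"area", "sex", "laxatives"}
        refs = report[report["is_reference"]]
        final_vars = tuple(fit.var_blocks) if fit is not None else ()
        for _, row in refs.iterrows():
            if row["variable"] in screen.included:
                assert row["bivariate_pr"] == "Ref"
            if row["variable"] in final_vars:
                assert row["multivariate_pr"] == "Ref"
        # screened-out variables carry no PR columns but keep prevalences
        out = report[~report["variable"].isin(screen.included)]
        if len(out):
            assert out["greater_pct"].notna().all()
            if "bivariate_pr" in out:
                assert out["bivariate_pr"].isna().all()
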