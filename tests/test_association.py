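"""Federated association analysis: standardization, GD-vs-OLS agreement, covariate ladder."""

import numpy as np
import pandas as pd
import pytest

from fedbioage.association import (
    COVARIATE_SETS,
    AssociationSpec,
    add_dummies,
    closed_form_pooled_ols,
    federated_linreg,
    federated_standardize,
    ladder_table,
    run_covariate_ladder,
    standardization_for,
    tidy_results,
)
from fedbioage.cohorts import CohortSpec, GeneratorTruth, generate_cohort
from fedbioage.scorers import score_metabolite_model, synthetic_metaboage_coefficients


def scored_tables(n_cohorts=3, n=400, seed0=0, brain_noise=2.0):
    """Cohorts with brainage/metaboage columns derived from the generator."""
    truth = GeneratorTruth()
    coeffs = synthetic_metaboage_coefficients(truth)
    tables = []
    for i in range(n_cohorts):
        spec = CohortSpec(
            f"C{i}", n, 45, 90, age_mean=60 + 4 * i, age_sd=9, lag_sd=2.0, seed=seed0 + i
        )
        t = generate_cohort(spec, truth)
        rng = np.random.default_rng(1000 + seed0 + i)
        t["brainage"] = t["age"] + t["true_brain_gap"] + rng.normal(0, brain_noise, n)
        t["metaboage"] = score_metabolite_model(coeffs, t)
        t["metabohealth"] = 0.0
        tables.append(t)
    return tables


@pytest.fixture(scope="module")
def tables():
    return scored_tables()


class TestStandardize:
    def test_single_cohort_matches_plain_stats(self, tables):
        stats = federated_standardize(tables[:1], ["age", "bmi"])
        assert stats.means["age"] == pytest.approx(tables[0]["age"].mean())
        assert stats.sds["bmi"] == pytest.approx(tables[0]["bmi"].std(ddof=1))

    def test_two_cohort_pooled_arithmetic(self):
        a = pd.DataFrame({"x": [0.0, 0.0]})
        b = pd.DataFrame({"x": [2.0, 2.0]})
        stats = federated_standardize([a, b], ["x"])
        assert stats.means["x"] == pytest.approx(1.0)
        assert stats.sds["x"] == pytest.approx(np.std([0, 0, 2, 2], ddof=1))

    def test_matches_concatenated_table(self, tables):
        variables = ["age", "bmi", "lag_time", "brainage", "metaboage"]
        stats = federated_standardize(tables, variables)
        pooled = pd.concat(tables, ignore_index=True)
        for v in variables:
            assert stats.means[v] == pytest.approx(pooled[v].mean(), abs=1e-12)
            assert stats.sds[v] == pytest.approx(pooled[v].std(ddof=1), abs=1e-12)

    def test_zero_variance_named(self, tables):
        t = tables[0].copy()
        t["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            federated_standardize([t], ["flat"])


class TestClosedForm:
    def test_partitioned_equals_concatenated(self, tables):
        spec = AssociationSpec(covariate_set="M4")
        stats = standardization_for(tables, spec)
        split = closed_form_pooled_ols(tables, spec, stats)
        pooled = closed_form_pooled_ols([pd.concat(tables, ignore_index=True)], spec, stats)
        np.testing.assert_allclose(split.betas, pooled.betas, atol=1e-12)

    def test_matches_statsmodels_oracle(self, tables):
        spec = AssociationSpec(covariate_set="M2")
        stats = standardization_for(tables, spec)
        res = closed_form_pooled_ols(tables, spec, stats)
        import statsmodels.api as sm

        pooled = pd.concat(tables, ignore_index=True)
        y = stats.standardize(pooled["metaboage"].to_numpy(), "metaboage")
        X = np.column_stack(
            [
                np.ones(len(pooled)),
                stats.standardize(pooled["brainage"].to_numpy(), "brainage"),
                stats.standardize(pooled["age"].to_numpy(), "age"),
            ]
        )
        fit = sm.OLS(y, X).fit()
        np.testing.assert_allclose(res.betas.to_numpy(), fit.params, atol=1e-10)
        np.testing.assert_allclose(res.ses.to_numpy(), fit.bse, atol=1e-10)
        np.testing.assert_allclose(res.pvalues.to_numpy(), fit.pvalues, atol=1e-10)

    def test_orthonormal_design_unit_beta(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(
            {
                "brainage": rng.normal(0, 1, 500),
                "metaboage": 0.0,
                "age": rng.normal(0, 1, 500),
            }
        )
        t["metaboage"] = t["brainage"]
        res = closed_form_pooled_ols([t], AssociationSpec(covariate_set="M2"))
        assert res.betas["brainage"] == pytest.approx(1.0, abs=1e-10)
        assert res.betas["age"] == pytest.approx(0.0, abs=1e-10)

    def test_perfect_fit_degenerate_flagged(self):
        t = pd.DataFrame({"brainage": [1.0, 2.0, 3.0], "metaboage": [1.0, 2.0, 3.0]})
        res = closed_form_pooled_ols([t], AssociationSpec(covariate_set="M1"))
        assert res.degenerate
        assert (res.ses == 0).all()

    def test_collinear_columns_named(self, tables):
        t = tables[0].copy()
        t["lag_time"] = t["age"]  # exact collinearity after standardization
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            closed_form_pooled_ols([t], AssociationSpec(covariate_set="M4"))


class TestFederatedGD:
    def test_single_cohort_trajectory_matches_hand_iteration(self):
        # 3-row design: replicate beta <- beta - eta*(2/n) X'(X beta - y) by hand
        t = pd.DataFrame({"brainage": [1.0, 2.0, 4.0], "metaboage": [1.5, 2.0, 4.5]})
        spec = AssociationSpec(covariate_set="M1", eta=0.1, max_rounds=3, tol=0.0, restarts=1, seed=5)
        stats = standardization_for([t], spec)
        res = federated_linreg([t], spec, stats)
        X = np.column_stack([np.ones(3), stats.standardize(t["brainage"].to_numpy(), "brainage")])
        y = stats.standardize(t["metaboage"].to_numpy(), "metaboage")
        beta = np.random.default_rng([5, 0]).normal(0.0, 0.01, 2)
        for _ in range(3):
            beta = beta - 0.1 * (2.0 / 3) * X.T @ (X @ beta - y)
        np.testing.assert_allclose(res.betas.to_numpy(), beta, atol=1e-12)

    def test_noise_free_standardized_slope_recovered(self):
        # construct y so the sample standardized slope is exactly 0.4:
        # y = 0.4 x_s + e with e orthogonal to x_s and var chosen for sd(y)=1
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 300)
        xs = (x - x.mean()) / x.std(ddof=1)
        z = rng.normal(0, 1, 300)
        e = z - (z @ xs / (xs @ xs)) * xs
        e = (e - e.mean()) / e.std(ddof=1) * np.sqrt(1 - 0.4**2)
        t = pd.DataFrame({"brainage": xs, "metaboage": 0.4 * xs + e})
        spec = AssociationSpec(covariate_set="M1", tol=1e-14, restarts=2, seed=1)
        res = federated_linreg([t], spec)
        assert res.betas["brainage"] == pytest.approx(0.4, abs=1e-6)

    def test_three_cohorts_match_closed_form(self, tables):
        spec = AssociationSpec(covariate_set="M2", tol=1e-12, max_rounds=50000, restarts=3, seed=2)
        fed = federated_linreg(tables, spec)
        ols = closed_form_pooled_ols(tables, spec)
        np.testing.assert_allclose(fed.betas, ols.betas, atol=1e-4)

    def test_intercept_self_check_near_zero(self, tables):
        res = federated_linreg(tables, AssociationSpec(covariate_set="M2", restarts=2, seed=0))
        assert abs(res.betas["intercept"]) < 1e-4

    def test_invariant_to_cohort_order_and_row_shuffle(self, tables):
        spec = AssociationSpec(covariate_set="M4", tol=1e-12, restarts=2, seed=4)
        a = federated_linreg(tables, spec)
        shuffled = [
            t.sample(frac=1.0, random_state=7).reset_index(drop=True) for t in reversed(tables)
        ]
        b = federated_linreg(shuffled, spec)
        np.testing.assert_allclose(a.betas, b.betas, atol=1e-9)

    def test_divergence_suggests_smaller_eta(self, tables):
        spec = AssociationSpec(covariate_set="M2", eta=50.0, restarts=1, max_rounds=500)
        with pytest.raises(FloatingPointError, match="eta"):
            federated_linreg(tables, spec)


class TestLadder:
    def test_covariate_set_definitions(self):
        assert COVARIATE_SETS["M1"] == []
        assert COVARIATE_SETS["M2"] == ["age"]
        assert COVARIATE_SETS["M4"] == ["age", "sex", "dm", "lag_time"]
        assert COVARIATE_SETS["M6"] == ["age", "sex", "dm", "lag_time", "bmi", "ec1", "ec3"]

    def test_dummy_encoding_relative_to_medium(self, tables):
        d = add_dummies(tables[0])
        assert set(np.unique(d[["ec1", "ec3"]])) <= {0.0, 1.0}
        medium = d["ec"] == "medium"
        assert (d.loc[medium, ["ec1", "ec3"]].to_numpy() == 0).all()

    def test_ladder_shape_and_terms(self, tables):
        results = run_covariate_ladder(tables, method="closed_form")
        assert list(results) == ["M1", "M2", "M3", "M4", "M5", "M6"]
        assert list(results["M1"].betas.index) == ["intercept", "brainage"]
        assert list(results["M4"].betas.index) == [
            "intercept", "brainage", "age", "sex", "dm", "lag_time",
        ]
        wide = ladder_table(results)
        assert wide.shape[0] == 6
        assert wide.columns[-1] == "mae"
        tidy = tidy_results(results)
        assert {"model", "term", "beta", "se", "p"} <= set(tidy.columns)

    def test_age_adjustment_attenuates_shared_age_signal(self):
        # world where both scores are age + independent noise: M1 slope is
        # strong and significant; adding age (M2) collapses it
        rng = np.random.default_rng(11)
        n = 1500
        age = rng.uniform(45, 90, n)
        t = pd.DataFrame(
            {
                "age": age,
                "brainage": age + rng.normal(0, 4, n),
                "metaboage": age + rng.normal(0, 6, n),
            }
        )
        res = run_covariate_ladder([t], method="closed_form", model_ids=("M1", "M2"))
        assert res["M1"].pvalues["brainage"] < 1e-10
        assert abs(res["M2"].betas["brainage"]) < 0.5 * abs(res["M1"].betas["brainage"])
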