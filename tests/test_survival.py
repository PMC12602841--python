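"""Cox profiling: grid-oracle agreement, gradient optimality, curve ordering."""

import numpy as np
import pandas as pd
import pytest

from fedbioage.association import add_dummies
from fedbioage.cohorts import CohortSpec, GeneratorTruth, generate_cohort
from fedbioage.survival import (
    QuartileProfile,
    compute_gaps,
    fit_cox,
    neg_log_partial_likelihood,
    partial_likelihood_gradient,
    predicted_survival,
    quartile_profiles,
    run_survival_suite,
)


def toy_frame(times, events, **covs):
    return pd.DataFrame({"t": times, "e": events, **covs})


@pytest.fixture(scope="module")
def scored(truth, scored_cohort):
    return compute_gaps(scored_cohort)


class TestGaps:
    def test_elementwise_subtraction(self):
        t = pd.DataFrame({"age": [65.0], "brainage": [70.0], "metaboage": [65.0]})
        g = compute_gaps(t)
        assert g.loc[0, "bag"] == 5.0 and g.loc[0, "mag"] == 0.0

    def test_identical_scores_zero_gap(self, scored_cohort):
        t = scored_cohort.copy()
        t["metaboage"] = t["age"]
        assert (compute_gaps(t)["mag"] == 0).all()

    def test_permutation_equivariant(self, scored):
        perm = np.random.default_rng(0).permutation(len(scored))
        g = compute_gaps(scored.iloc[perm])
        np.testing.assert_array_equal(g["bag"].to_numpy(), scored["bag"].to_numpy()[perm])

    def test_missing_score_column_rejected(self, small_cohort):
        with pytest.raises(KeyError, match="brainage"):
            compute_gaps(small_cohort)


class TestFitCoxOracle:
    def test_one_covariate_matches_dense_grid(self):
        # 4 subjects, finite MLE; oracle = dense grid over the explicit
        # Breslow partial likelihood
        df = toy_frame([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 0], x=[1.0, 0.0, 1.0, 0.0])
        fit = fit_cox(df, "t", "e", ["x"])
        grid = np.linspace(-5, 5, 20001)
        X = df[["x"]].to_numpy()
        nll = [
            neg_log_partial_likelihood(np.array([b]), df["t"].to_numpy(), df["e"].to_numpy(), X)
            for b in grid
        ]
        assert fit.coefficients["x"] == pytest.approx(grid[int(np.argmin(nll))], abs=1e-3)

    def test_two_covariates_match_dense_grid(self):
        df = toy_frame(
            [1.0, 2.0, 3.0, 4.0, 5.0],
            [1, 1, 0, 1, 1],
            x=[1.0, 0.0, 1.0, 0.0, 0.0],
            z=[0.2, 0.6, 0.6, 1.0, 0.1],
        )
        fit = fit_cox(df, "t", "e", ["x", "z"])
        grid = np.linspace(-5, 5, 301)
        X = df[["x", "z"]].to_numpy()
        best, best_val = None, np.inf
        for bx in grid:
            for bz in grid:
                v = neg_log_partial_likelihood(
                    np.array([bx, bz]), df["t"].to_numpy(), df["e"].to_numpy(), X
                )
                if v < best_val:
                    best, best_val = (bx, bz), v
        res = 10.0 / 300
        assert fit.coefficients["x"] == pytest.approx(best[0], abs=res)
        assert fit.coefficients["z"] == pytest.approx(best[1], abs=res)

    def test_gradient_vanishes_at_optimum(self, scored):
        fit = fit_cox(scored, "time_mort", "event_mort", ["bag", "mag", "age"])
        g, _ = partial_likelihood_gradient(
            fit.coefficients.to_numpy(),
            scored["time_mort"].to_numpy(),
            scored["event_mort"].to_numpy(),
            scored[["bag", "mag", "age"]].to_numpy(),
        )
        assert np.linalg.norm(g) < 1e-8

    def test_duplicated_rows_leave_coefficients_unchanged(self, scored):
        fit1 = fit_cox(scored, "time_mort", "event_mort", ["bag", "age"])
        doubled = pd.concat([scored, scored], ignore_index=True)
        fit2 = fit_cox(doubled, "time_mort", "event_mort", ["bag", "age"])
        np.testing.assert_allclose(
            fit1.coefficients.to_numpy(), fit2.coefficients.to_numpy(), atol=1e-6
        )

    def test_null_covariate_usually_within_two_se_of_zero(self, truth):
        t = generate_cohort(
            CohortSpec("N", 1500, 45, 90, age_mean=65, age_sd=10, seed=21), truth
        )
        hits = 0
        for rep in range(5):
            t["noise"] = np.random.default_rng(rep).normal(0, 1, len(t))
            fit = fit_cox(t, "time_mort", "event_mort", ["noise"])
            hits += abs(fit.coefficients["noise"]) < 2 * fit.ses["noise"]
        assert hits >= 4

    def test_no_events_rejected(self, scored):
        t = scored.copy()
        t["event_mort"] = 0
        with pytest.raises(ValueError, match="events"):
            fit_cox(t, "time_mort", "event_mort", ["bag"])

    def test_nonpositive_times_rejected(self, scored):
        t = scored.copy()
        t.loc[t.index[0], "time_mort"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            fit_cox(t, "time_mort", "event_mort", ["bag"])


class TestCurves:
    @pytest.fixture(scope="class")
    def fit_and_profiles(self, truth):
        # large enough that both fitted gap coefficients are reliably positive
        t = generate_cohort(
            CohortSpec("C", 1200, 45, 90, age_mean=65, age_sd=10, seed=31), truth
        )
        t["bag"] = t["true_brain_gap"]
        t["mag"] = t["true_metab_gap"]
        fit = fit_cox(t, "time_mort", "event_mort", ["bag", "mag", "age"])
        profiles = quartile_profiles(t, ("bag", "mag"), ["age"])
        return fit, profiles

    def test_four_profiles_with_ordered_quartiles(self, fit_and_profiles):
        _, profiles = fit_and_profiles
        assert len(profiles) == 4
        bag_vals = sorted({p.row["bag"] for p in profiles})
        assert bag_vals[0] < bag_vals[1]

    def test_curves_start_at_one_and_decrease(self, fit_and_profiles):
        fit, profiles = fit_and_profiles
        for p in profiles:
            s = predicted_survival(fit, p)
            assert s.iloc[0] <= 1.0 + 1e-12
            assert (np.diff(s.to_numpy()) <= 1e-12).all()

    def test_concordant_profiles_bracket_mixed_ones(self, fit_and_profiles):
        fit, profiles = fit_and_profiles
        # with positive coefficients for both gaps the high/high profile has
        # the lowest survival, low/low the highest, mixed in between
        assert fit.coefficients["bag"] > 0 and fit.coefficients["mag"] > 0
        curves = {(p.bag_level, p.mag_level): predicted_survival(fit, p) for p in profiles}
        low, high = curves[("Q1", "Q1")], curves[("Q3", "Q3")]
        for key in [("Q1", "Q3"), ("Q3", "Q1")]:
            mid = curves[key]
            assert (high.to_numpy() <= mid.to_numpy() + 1e-12).all()
            assert (mid.to_numpy() <= low.to_numpy() + 1e-12).all()

    def test_profile_mismatch_rejected(self, fit_and_profiles):
        fit, _ = fit_and_profiles
        bad = QuartileProfile("Q1", "Q1", {"bag": 0.0, "mag": 0.0})  # missing age
        with pytest.raises(ValueError, match="match"):
            predicted_survival(fit, bad)

    def test_zero_linear_predictor_gives_baseline_survival(self, scored):
        # center the covariate so a zero profile is the baseline itself
        t = scored.copy()
        t["bag0"] = t["bag"] - 0.0
        fit = fit_cox(t, "time_mort", "event_mort", ["bag0"])
        prof = QuartileProfile("Q1", "Q1", {"bag0": 0.0})
        s = predicted_survival(fit, prof).to_numpy()
        expected = np.exp(-fit.baseline_cumhaz.to_numpy())
        np.testing.assert_allclose(s, expected, atol=1e-8)


class TestSuite:
    def test_pairwise_fits_emit_four_profile_curves(self, scored):
        report = run_survival_suite(
            scored, outcomes=("mortality",), covariate_sets=("age_only",)
        )
        for key, frame in report["curves"].items():
            assert frame.shape[1] == 4
        coefs = report["coefficients"]
        assert set(coefs["model"].str.split(":").str[0]) == {"separate", "pairwise"}

    def test_missing_outcome_skipped_with_note(self, scored):
        t = scored.copy()
        t["time_dem"] = np.nan
        t["event_dem"] = np.nan
        report = run_survival_suite(t, outcomes=("dementia",))
        assert report["coefficients"].empty
        assert any("dementia" in s for s in report["skipped"])

    def test_separate_vs_pairwise_coefficients_stable_for_independent_gaps(self, scored):
        report = run_survival_suite(
            scored, outcomes=("mortality",), score_pairs=(("bag", "mag"),),
            covariate_sets=("age_only",),
        )
        c = report["coefficients"]
        sep = c[(c["model"] == "separate:bag") & (c["term"] == "bag")]["beta"].iloc[0]
        pair = c[(c["model"] == "pairwise:bag+mag") & (c["term"] == "bag")]["beta"].iloc[0]
        se = c[(c["model"] == "separate:bag") & (c["term"] == "bag")]["se"].iloc[0]
        assert abs(sep - pair) < 2 * se
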