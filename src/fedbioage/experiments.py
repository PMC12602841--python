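"""Named study-condition experiments over the simulated federation.

Each function runs one self-contained experiment at desk scale — the checks a
reader would use to convince themselves the machinery is correct (exact
federated/centralized identities, oracle agreement, parameter recovery) and
that the qualitative multi-cohort phenomena (age confounding of the score
association, cross-cohort generalization of the federated predictor, survival
separation of the gap-score quartile profiles) emerge from the generator's
assumptions. The analysis drivers and the acceptance script both call these.

All randomness flows from the single ``seed`` argument.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import bias as bias_mod
from .association import (
    AssociationSpec,
    add_dummies,
    closed_form_pooled_ols,
    federated_linreg,
    federated_standardize,
    run_covariate_ladder,
    standardization_for,
)
from .cohorts import (
    BRAIN_COLS,
    CohortSpec,
    GeneratorTruth,
    generate_cohort,
    generate_federation,
    split_train_val,
)
from .federation import FederationConfig, aggregate, client_seed, run_federated
from .predictors import AgePredictor, PredictorConfig, mae, predict_age
from .scorers import score_metabolite_model, synthetic_metaboage_coefficients
from .survival import (
    fit_cox,
    neg_log_partial_likelihood,
    predicted_survival,
    quartile_profiles,
)


def _sub_seed(seed: int, tag: str, k: int = 0) -> int:
    import hashlib

    digest = hashlib.sha256(f"{seed}|{tag}|{k}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _exact_score_tables(truth: GeneratorTruth, specs: list[CohortSpec]) -> list[pd.DataFrame]:
    """Cohorts scored with zero measurement noise: gap columns equal the truth."""
    tables = []
    for t in generate_federation(specs, truth):
        t["brainage"] = t["age"] + t["true_brain_gap"]
        t["metaboage"] = t["age"] + t["true_metab_gap"]
        tables.append(add_dummies(t))
    return tables


# ---------------------------------------------------------------------------
# exact identities and oracle agreement


def fedavg_centralized_identity(seed: int, rounds: int = 5) -> dict:
    """Max elementwise gap between the federated and centralized trajectories.

    Linear model, full-batch gradient steps, one local step per round,
    sample-size-weighted aggregation: the federated round-t parameters must
    equal centralized gradient descent on the pooled table at every round.
    """
    truth = GeneratorTruth()
    specs = [
        CohortSpec(f"C{i}", 200 + 100 * i, 45, 90, age_mean=60 + 4 * i, age_sd=9,
                   seed=_sub_seed(seed, "fedavg", i))
        for i in range(3)
    ]
    tables = generate_federation(specs, truth)
    pooled = pd.concat(tables, ignore_index=True)
    model = AgePredictor(PredictorConfig(kind="linear", learning_rate=1e-4, optimizer="sgd"))
    fed = model.init_params(_sub_seed(seed, "init"))
    central = fed.with_values(fed.values.copy())
    sizes = [len(t) for t in tables]
    max_gap = 0.0
    for rnd in range(1, rounds + 1):
        locals_ = []
        for spec, t in zip(specs, tables):
            upd, _ = model.train(fed, t, 1, None, seed=client_seed(seed, spec.name, rnd))
            locals_.append(upd)
        fed = aggregate(locals_, sizes, "n_weighted")
        central, _ = model.train(central, pooled, 1, None)
        max_gap = max(max_gap, float(np.max(np.abs(fed.values - central.values))))
    return {"max_param_gap": max_gap, "rounds": rounds, "n": sum(sizes)}


def federated_vs_closed_form(seed: int, n_per_cohort: int = 1000) -> dict:
    """Gradient-descent betas vs pooled-OLS oracle, and partition additivity."""
    truth = GeneratorTruth()
    specs = [
        CohortSpec(f"C{i}", n_per_cohort, 45, 90, age_mean=60 + 4 * i, age_sd=9, lag_sd=2.0,
                   seed=_sub_seed(seed, "fvo", i))
        for i in range(3)
    ]
    tables = _exact_score_tables(truth, specs)
    spec = AssociationSpec(covariate_set="M2", tol=1e-13, max_rounds=100000, restarts=3,
                           seed=_sub_seed(seed, "fvo-fit"))
    stats = standardization_for(tables, spec)
    fed = federated_linreg(tables, spec, stats)
    ols = closed_form_pooled_ols(tables, spec, stats)
    pooled = closed_form_pooled_ols([pd.concat(tables, ignore_index=True)], spec, stats)
    return {
        "fed_vs_ols_max_beta_gap": float(np.max(np.abs(fed.betas - ols.betas))),
        "partition_max_beta_gap": float(np.max(np.abs(ols.betas - pooled.betas))),
        "n": stats.n_total,
        "beta_brainage": float(ols.betas["brainage"]),
    }


def parameter_recovery(seed: int, n_reps: int = 100) -> dict:
    """Coverage of generator truth by the association and Cox estimators.

    Association: with independent gaps and exact scores, the true age-adjusted
    coefficient of the imaging score is 0; count replicates whose estimate
    falls within 2 SE of 0. Cox: mortality log-HRs for both gaps (fit with the
    full, correctly-specified covariate set) within 2 SE of the generator's
    values.
    """
    truth = GeneratorTruth()
    assoc_hits = cox_bag_hits = cox_mag_hits = 0
    for r in range(n_reps):
        specs = [
            CohortSpec(f"C{i}", 800, 45, 90, age_mean=60 + 4 * i, age_sd=9, lag_sd=2.0,
                       seed=_sub_seed(seed, "rec-a", 3 * r + i))
            for i in range(3)
        ]
        tables = _exact_score_tables(truth, specs)
        res = closed_form_pooled_ols(tables, AssociationSpec(covariate_set="M2"))
        assoc_hits += abs(res.betas["brainage"]) <= 2 * res.ses["brainage"]

        cox_spec = CohortSpec("S", 2000, 45, 90, age_mean=65, age_sd=10, lag_sd=2.0,
                              seed=_sub_seed(seed, "rec-c", r))
        t = add_dummies(generate_cohort(cox_spec, truth))
        t["bag"] = t["true_brain_gap"]
        t["mag"] = t["true_metab_gap"]
        fit = fit_cox(t, "time_mort", "event_mort",
                      ["bag", "mag", "age", "sex", "dm", "bmi", "ec1", "ec3"])
        cox_bag_hits += abs(fit.coefficients["bag"] - truth.loghr_mort_bag) <= 2 * fit.ses["bag"]
        cox_mag_hits += abs(fit.coefficients["mag"] - truth.loghr_mort_mag) <= 2 * fit.ses["mag"]
    return {
        "assoc_beta_cover_frac": assoc_hits / n_reps,
        "cox_bag_cover_frac": cox_bag_hits / n_reps,
        "cox_mag_cover_frac": cox_mag_hits / n_reps,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# qualitative multi-cohort patterns


def age_confounding_pattern(seed: int, n_reps: int = 10) -> dict:
    """Both scores share only the age signal: the unadjusted association is
    significant, and adding age attenuates it by at least half."""
    sig = atten = 0
    betas_m1, betas_m2 = [], []
    for r in range(n_reps):
        rng = np.random.default_rng(_sub_seed(seed, "conf", r))
        tables = []
        for i in range(3):
            n = 500
            age = rng.uniform(45, 90, n)
            tables.append(
                pd.DataFrame(
                    {
                        "age": age,
                        "brainage": age + rng.normal(0, 4, n),
                        "metaboage": age + rng.normal(0, 6, n),
                    }
                )
            )
        fit_kwargs = dict(restarts=3, tol=1e-10, seed=_sub_seed(seed, "conf-fit", r))
        m1 = federated_linreg(tables, AssociationSpec(covariate_set="M1", **fit_kwargs))
        m2 = federated_linreg(tables, AssociationSpec(covariate_set="M2", **fit_kwargs))
        sig += m1.pvalues["brainage"] <= 0.05
        atten += abs(m2.betas["brainage"]) <= 0.5 * abs(m1.betas["brainage"])
        betas_m1.append(m1.betas["brainage"])
        betas_m2.append(m2.betas["brainage"])
    return {
        "m1_significant_frac": sig / n_reps,
        "attenuated_frac": atten / n_reps,
        "mean_beta_m1": float(np.mean(betas_m1)),
        "mean_beta_m2": float(np.mean(betas_m2)),
        "n_reps": n_reps,
    }


def bias_correction_exactness(seed: int) -> dict:
    """Slope of the corrected gap on age, on the fit set (exactly zero)."""
    from scipy import stats as sps

    truth = GeneratorTruth()
    spec = CohortSpec("B", 600, 45, 90, age_mean=65, age_sd=10, seed=_sub_seed(seed, "bias"))
    t = generate_cohort(spec, truth)
    train, val = split_train_val(t, 0.8, seed=_sub_seed(seed, "bias-split"))
    cfg = PredictorConfig(kind="linear", learning_rate=5e-3, optimizer="adam")
    model = AgePredictor(cfg)
    params, _ = model.train(model.init_params(_sub_seed(seed, "bias-init")), train, 30, 8,
                            seed=_sub_seed(seed, "bias-train"))
    pred = predict_age(params, train, cfg)
    age = train["age"].to_numpy(dtype=float)
    correction = bias_mod.fit_bias_correction(pred, age, fit_source="B")
    corrected = bias_mod.apply_correction(correction, pred, age)
    slope = sps.linregress(age, corrected - age).slope
    return {
        "post_correction_gap_slope": float(abs(slope)),
        "pre_correction_bias_slope": float(correction.slope),
        "n": len(train),
    }


def _shifted_cohort_specs(seed: int, rep: int, n: int = 400):
    """Two age-shifted training cohorts and a held-out cohort spanning both."""
    mk = lambda name, lo, hi, k: CohortSpec(
        name, n, lo, hi, age_shape="uniform", site_offset_scale=2.0,
        seed=_sub_seed(seed, "gen-cohort", 10 * rep + k),
    )
    return mk("young", 45, 62, 0), mk("old", 63, 80, 1), mk("held_out", 50, 75, 2)


def generalization_pattern(seed: int, n_reps: int = 10) -> dict:
    """Held-out-cohort error of the federated model vs single-cohort models.

    Training cohorts occupy disjoint age ranges; the held-out cohort spans
    both. Count replicates where the federated predictor's MAE on the held-out
    cohort is no worse than either locally trained model's.
    """
    truth = GeneratorTruth()
    fed_cfg_base = FederationConfig(rounds=20, local_epochs=3, batch_size=8,
                                    aggregation="n_weighted")
    wins = 0
    fed_maes, local_maes = [], {"young": [], "old": []}
    for r in range(n_reps):
        spec_a, spec_b, spec_c = _shifted_cohort_specs(seed, r)
        tab = {s.name: generate_cohort(s, truth) for s in (spec_a, spec_b, spec_c)}

        def train_model(train_cohorts: list[str], k: int):
            stats = federated_standardize([tab[c] for c in train_cohorts],
                                          list(BRAIN_COLS) + ["age"])
            def std(t):
                t = t.copy()
                for c in BRAIN_COLS:
                    t[c] = (t[c] - stats.means[c]) / stats.sds[c]
                return t
            cfg = PredictorConfig(kind="linear", learning_rate=5e-3,
                                  output_bias_init=stats.means["age"])
            model = AgePredictor(cfg)
            clients = []
            for c in train_cohorts:
                tr, va = split_train_val(std(tab[c]), 0.8,
                                         seed=_sub_seed(seed, "gen-split", 10 * r + k))
                clients.append((c, tr, va))
            fc = dataclasses.replace(fed_cfg_base, seed=_sub_seed(seed, "gen-fed", 10 * r + k))
            params, _ = run_federated(clients, lambda: model, fc)
            held = std(tab["held_out"])
            return mae(model.predict(params, held), held["age"].to_numpy(dtype=float))

        fed_mae = train_model(["young", "old"], 0)
        mae_young = train_model(["young"], 1)
        mae_old = train_model(["old"], 2)
        wins += fed_mae <= mae_young and fed_mae <= mae_old
        fed_maes.append(fed_mae)
        local_maes["young"].append(mae_young)
        local_maes["old"].append(mae_old)
    return {
        "federated_best_frac": wins / n_reps,
        "mean_federated_mae": float(np.mean(fed_maes)),
        "mean_local_young_mae": float(np.mean(local_maes["young"])),
        "mean_local_old_mae": float(np.mean(local_maes["old"])),
        "n_reps": n_reps,
    }


def survival_patterns(seed: int, n_reps: int = 100) -> dict:
    """Quartile-profile curve ordering and the brain-only dementia signal.

    One mortality fit checks that, with positive true log-HRs, the predicted
    survival curves order as high/high < mixed < low/low at every time point.
    Across replicates, dementia fits must find the brain gap significant and
    the metabolic gap non-significant (its true dementia log-HR is zero).
    """
    truth = GeneratorTruth()

    def cohort(r, followup):
        spec = CohortSpec("S", 1500, 45, 90, age_mean=65, age_sd=10, lag_sd=2.0,
                          followup_years=followup, seed=_sub_seed(seed, "surv", r))
        t = add_dummies(generate_cohort(spec, truth))
        t["bag"] = t["true_brain_gap"]
        t["mag"] = t["true_metab_gap"]
        return t

    t0 = cohort(0, 10.0)
    fit = fit_cox(t0, "time_mort", "event_mort", ["bag", "mag", "age"])
    n_dem = 2000  # dementia replicates sized so the Wald test is in its asymptotic regime
    profiles = quartile_profiles(t0, ("bag", "mag"), ["age"])
    curves = {(p.bag_level, p.mag_level): predicted_survival(fit, p).to_numpy() for p in profiles}
    tol = 1e-12
    ordering_ok = bool(
        np.all(curves[("Q3", "Q3")] <= curves[("Q1", "Q3")] + tol)
        and np.all(curves[("Q3", "Q3")] <= curves[("Q3", "Q1")] + tol)
        and np.all(curves[("Q1", "Q3")] <= curves[("Q1", "Q1")] + tol)
        and np.all(curves[("Q3", "Q1")] <= curves[("Q1", "Q1")] + tol)
    )

    bag_sig = mag_nonsig = 0
    for r in range(n_reps):
        spec = CohortSpec("S", n_dem, 45, 90, age_mean=65, age_sd=10, lag_sd=2.0,
                          followup_years=15.0, seed=_sub_seed(seed, "surv", 100 + r))
        t = add_dummies(generate_cohort(spec, truth))
        t["bag"] = t["true_brain_gap"]
        t["mag"] = t["true_metab_gap"]
        dem = fit_cox(t, "time_dem", "event_dem", ["bag", "mag", "age"])
        bag_sig += dem.pvalues["bag"] <= 0.05
        mag_nonsig += dem.pvalues["mag"] > 0.05
    return {
        "curve_ordering_ok": float(ordering_ok),
        "mort_loghr_bag": float(fit.coefficients["bag"]),
        "mort_loghr_mag": float(fit.coefficients["mag"]),
        "dementia_bag_significant_frac": bag_sig / n_reps,
        "dementia_mag_nonsignificant_frac": mag_nonsig / n_reps,
        "n_reps": n_reps,
    }


def cox_grid_oracle(seed: int) -> dict:
    """fit_cox vs dense grid maximization of the explicit partial likelihood."""
    df1 = pd.DataFrame(
        {"t": [1.0, 2.0, 3.0, 4.0], "e": [1, 1, 1, 0], "x": [1.0, 0.0, 1.0, 0.0]}
    )
    fit1 = fit_cox(df1, "t", "e", ["x"])
    grid = np.linspace(-5, 5, 20001)
    X1 = df1[["x"]].to_numpy()
    nll = [neg_log_partial_likelihood(np.array([b]), df1["t"].to_numpy(), df1["e"].to_numpy(), X1)
           for b in grid]
    gap_1d = abs(float(fit1.coefficients["x"]) - float(grid[int(np.argmin(nll))]))

    df2 = pd.DataFrame(
        {
            "t": [1.0, 2.0, 3.0, 4.0, 5.0],
            "e": [1, 1, 0, 1, 1],
            "x": [1.0, 0.0, 1.0, 0.0, 0.0],
            "z": [0.2, 0.6, 0.6, 1.0, 0.1],
        }
    )
    fit2 = fit_cox(df2, "t", "e", ["x", "z"])
    g2 = np.linspace(-5, 5, 401)
    X2 = df2[["x", "z"]].to_numpy()
    best, best_val = None, np.inf
    for bx in g2:
        vals = [
            neg_log_partial_likelihood(np.array([bx, bz]), df2["t"].to_numpy(),
                                       df2["e"].to_numpy(), X2)
            for bz in g2
        ]
        j = int(np.argmin(vals))
        if vals[j] < best_val:
            best, best_val = (bx, g2[j]), vals[j]
    gap_2d = max(abs(float(fit2.coefficients["x"]) - best[0]),
                 abs(float(fit2.coefficients["z"]) - best[1]))
    return {"grid_gap_1d": gap_1d, "grid_gap_2d": gap_2d,
            "grid_resolution_1d": float(grid[1] - grid[0]),
            "grid_resolution_2d": float(g2[1] - g2[0])}
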