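"""End-to-end scenario orchestration.

``run_pipeline`` sequences the whole analysis on one synthetic federation:

    simulate -> select/split -> federated + local predictor training ->
    age-bias correction -> score computation -> association ladder ->
    survival suite

writing every artifact (CSV/JSON) plus a manifest with content hashes and the
seeds used, so a rerun with the same config is bit-identical. The default
scenario mirrors a three-cohort study: a large general-population cohort with
long mortality/dementia follow-up, a younger cohort without long-term
follow-up that still contributes training data, and a small
healthy-aging cohort used only as the external test site (blood draw and scan
simultaneous, so every lag time is zero).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, bias, cohorts, federation, predictors, scorers, survival


@dataclass(frozen=True)
class ScenarioConfig:
    cohort_specs: tuple[cohorts.CohortSpec, ...]
    truth: cohorts.GeneratorTruth = field(default_factory=cohorts.GeneratorTruth)
    federation: federation.FederationConfig = field(
        default_factory=lambda: federation.FederationConfig(
            rounds=20, local_epochs=3, batch_size=8, aggregation="equal"
        )
    )
    predictor: predictors.PredictorConfig = field(
        default_factory=lambda: predictors.PredictorConfig(
            kind="mlp", hidden_sizes=(16,), dropout_last=0.5, learning_rate=1e-3, lr_decay=1e-2
        )
    )
    training_cohorts: tuple[str, ...] = ()  # empty = all but the last spec
    test_frac: float = 0.5  # per training cohort, fraction held out as test
    train_frac: float = 0.8  # within the development pool
    max_abs_lag: float = 7.0
    eta: float = 0.1
    restarts: int = 10
    master_seed: int = 0

    def training_names(self) -> tuple[str, ...]:
        if self.training_cohorts:
            return self.training_cohorts
        return tuple(s.name for s in self.cohort_specs[:-1])


def default_scenario(master_seed: int = 0, scale: float = 1.0) -> ScenarioConfig:
    """Three desk-scale cohorts with realistic, heterogeneous demographics.

    Age distributions, sex/diabetes/education mixes, lag-time distributions
    and follow-up horizons differ by site; the external cohort has zero lag
    for everyone and the younger cohort collects no long-term outcomes.
    """
    n = lambda base: max(int(round(base * scale)), 30)
    specs = (
        cohorts.CohortSpec(
            name="RS",
            n=n(800),
            age_low=46,
            age_high=96,
            age_mean=67.5,
            age_sd=9.5,
            sex_frac_female=0.571,
            dm_prevalence=0.088,
            lag_mean=-1.39,
            lag_sd=3.22,
            ec_freqs=(0.463, 0.297, 0.240),
            site_offset_scale=2.0,
            followup_years=10.0,
            seed=master_seed * 7919 + 1,
        ),
        cohorts.CohortSpec(
            name="TMS",
            n=n(750),
            age_low=40,
            age_high=75,
            age_mean=60.3,
            age_sd=8.4,
            sex_frac_female=0.490,
            dm_prevalence=0.222,
            lag_mean=2.2,
            lag_sd=1.3,
            ec_freqs=(0.304, 0.289, 0.407),
            site_offset_scale=2.0,
            followup_years=5.0,
            collect_mortality=False,
            collect_dementia=False,
            seed=master_seed * 7919 + 2,
        ),
        cohorts.CohortSpec(
            name="LLS",
            n=n(300),
            age_low=45,
            age_high=84,
            age_mean=65.5,
            age_sd=6.6,
            sex_frac_female=0.522,
            dm_prevalence=0.058,
            lag_mean=0.0,
            lag_sd=0.0,
            ec_freqs=(0.552, 0.086, 0.362),
            site_offset_scale=2.0,
            followup_years=13.0,
            seed=master_seed * 7919 + 3,
        ),
    )
    return ScenarioConfig(cohort_specs=specs, master_seed=master_seed)


def scenario_from_yaml(path) -> ScenarioConfig:
    """Build a scenario from a YAML file of nested config mappings."""
    raw = yaml.safe_load(Path(path).read_text())
    spec_dicts = raw.pop("cohorts")
    for s in spec_dicts:
        if "ec_freqs" in s:
            s["ec_freqs"] = tuple(s["ec_freqs"])
    specs = tuple(cohorts.CohortSpec(**s) for s in spec_dicts)
    truth = cohorts.GeneratorTruth(**raw.pop("truth", {}))
    fed = federation.FederationConfig(**raw.pop("federation", {}))
    pred_kwargs = raw.pop("predictor", {})
    for key in ("hidden_sizes", "feature_cols"):
        if key in pred_kwargs:
            pred_kwargs[key] = tuple(pred_kwargs[key])
    pred = predictors.PredictorConfig(**pred_kwargs)
    if "training_cohorts" in raw:
        raw["training_cohorts"] = tuple(raw["training_cohorts"])
    return ScenarioConfig(cohort_specs=specs, truth=truth, federation=fed, predictor=pred, **raw)


def scenario_to_yaml(config: ScenarioConfig, path) -> None:
    doc = {
        "cohorts": [dataclasses.asdict(s) for s in config.cohort_specs],
        "truth": {
            k: v for k, v in dataclasses.asdict(config.truth).items() if not isinstance(v, np.ndarray)
        },
        "federation": dataclasses.asdict(config.federation),
        "predictor": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config.predictor).items()
        },
        "training_cohorts": list(config.training_names()),
        "test_frac": config.test_frac,
        "train_frac": config.train_frac,
        "max_abs_lag": config.max_abs_lag,
        "eta": config.eta,
        "restarts": config.restarts,
        "master_seed": config.master_seed,
    }
    doc["cohorts"] = [
        {k: (list(v) if isinstance(v, tuple) else v) for k, v in s.items()} for s in doc["cohorts"]
    ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _score_table(table, params, config, age_coeffs, mort_coeffs):
    out = table.copy()
    out["brainage"] = predictors.predict_age(params, out, config)
    out["metaboage"] = scorers.score_metabolite_model(age_coeffs, out)
    out["metabohealth"] = scorers.score_metabolite_model(mort_coeffs, out)
    return out


def run_pipeline(config: ScenarioConfig, outdir) -> dict:
    """Execute the full scenario; returns the in-memory report bundle.

    Every stage error is re-raised with the stage name prepended.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str):
        path = outdir / name
        df.to_csv(path, index=True if df.index.name or df.index.nlevels > 1 else False)
        written.append(path)

    stage = "simulate"
    try:
        tables = cohorts.generate_federation(list(config.cohort_specs), config.truth)
        by_name = {s.name: t for s, t in zip(config.cohort_specs, tables)}
        for name, t in by_name.items():
            path = outdir / f"cohort_{name}.csv"
            cohorts.write_cohort_csv(t, path)
            written.append(path)

        stage = "select_split"
        train_names = config.training_names()
        dev, val, test = {}, {}, {}
        for i, name in enumerate(by_name):
            analysis = cohorts.select_analysis_set(by_name[name], config.max_abs_lag)
            if name in train_names:
                pool, tst = cohorts.split_train_val(
                    analysis, 1.0 - config.test_frac, seed=config.master_seed * 31 + i
                )
                tr, va = cohorts.split_train_val(
                    pool, config.train_frac, seed=config.master_seed * 31 + 100 + i
                )
                dev[name], val[name], test[name] = tr, va, tst
            else:
                test[name] = analysis

        stage = "standardize_features"
        # federated feature scaling: pooled brain-feature means/SDs from the
        # training cohorts' sufficient statistics; the head bias starts at the
        # pooled mean age so the model learns deviations from it
        feat_cols = list(config.predictor.feature_cols)
        feat_stats = association.federated_standardize(
            [dev[n] for n in train_names], feat_cols + ["age"]
        )

        def std_features(t: pd.DataFrame) -> pd.DataFrame:
            t = t.copy()
            for c in feat_cols:
                t[c] = (t[c] - feat_stats.means[c]) / feat_stats.sds[c]
            return t

        dev = {k: std_features(v) for k, v in dev.items()}
        val = {k: std_features(v) for k, v in val.items()}
        test_std = {k: std_features(v) for k, v in test.items()}
        predictor_cfg = dataclasses.replace(
            config.predictor, output_bias_init=feat_stats.means["age"]
        )

        stage = "train_federated"
        model = predictors.AgePredictor(predictor_cfg)
        clients = [(name, dev[name], val[name]) for name in train_names]
        fed_cfg = dataclasses.replace(config.federation, seed=config.master_seed)
        fed_params, fed_log = federation.run_federated(clients, lambda: model, fed_cfg)
        fed_log.write_csv(outdir / "round_log.csv")
        written.append(outdir / "round_log.csv")
        federation.write_checkpoint(fed_params, outdir / "federated_model")

        stage = "train_local"
        # same round protocol with a single client, so a one-cohort scenario
        # reduces the federated and local models to the identical trajectory
        local_params = {}
        for name in train_names:
            params, _ = federation.run_federated(
                [(name, dev[name], val[name])], lambda: model, fed_cfg
            )
            local_params[name] = params

        stage = "evaluate_mae_grid"
        grid_rows = []
        models = {**{f"local:{n}": p for n, p in local_params.items()}, "federated": fed_params}
        for eval_name, eval_table in test_std.items():
            for model_name, params in models.items():
                pred = predictors.predict_age(params, eval_table, predictor_cfg)
                age = eval_table["age"].to_numpy(dtype=float)
                lo, hi = predictors.bootstrap_ci_mae(pred, age, seed=config.master_seed * 17 + 5)
                grid_rows.append(
                    {
                        "cohort": eval_name,
                        "subset": "test",
                        "model": model_name,
                        "mae": predictors.mae(pred, age),
                        "ci_low": lo,
                        "ci_high": hi,
                        "n": len(eval_table),
                    }
                )
        mae_grid = pd.DataFrame(grid_rows)
        emit(mae_grid, "mae_grid.csv")

        stage = "bias_correction"
        bias_rows = []
        corrections = {}
        for model_name, params in models.items():
            source = model_name.split(":")[-1]
            fit_tables = [dev[source]] if model_name.startswith("local") else [dev[n] for n in train_names]
            fit_tab = pd.concat(fit_tables, ignore_index=True)
            fit_pred = predictors.predict_age(params, fit_tab, predictor_cfg)
            model = bias.fit_bias_correction(fit_pred, fit_tab["age"].to_numpy(float), source)
            corrections[model_name] = model
            for eval_name, eval_table in test_std.items():
                pred = predictors.predict_age(params, eval_table, predictor_cfg)
                rep = bias.correction_report(model, pred, eval_table["age"].to_numpy(float))
                bias_rows.append({"model": model_name, "cohort": eval_name, **rep})
        emit(pd.DataFrame(bias_rows), "bias_correction.csv")

        stage = "scoring"
        age_coeffs = scorers.synthetic_metaboage_coefficients(config.truth)
        mort_coeffs = scorers.synthetic_metabohealth_coefficients(config.truth)
        scored = {
            name: _score_table(t, fed_params, predictor_cfg, age_coeffs, mort_coeffs)
            for name, t in test_std.items()
        }

        stage = "association"
        assoc_tables = list(scored.values())
        ladders = {}
        for response in ("metaboage", "metabohealth"):
            results = association.run_covariate_ladder(
                assoc_tables,
                response=response,
                method="federated",
                eta=config.eta,
                restarts=config.restarts,
                seed=config.master_seed * 613 + 9,
            )
            ladders[response] = results
            emit(association.tidy_results(results), f"association_{response}.csv")
            emit(association.ladder_table(results).reset_index(), f"association_{response}_table.csv")

        stage = "survival"
        surv_reports = {}
        for name, tab in scored.items():
            if tab["event_mort"].dropna().empty and tab["event_dem"].dropna().empty:
                continue
            gaps = survival.compute_gaps(association.add_dummies(tab))
            surv_reports[name] = survival.run_survival_suite(gaps)
            emit(surv_reports[name]["coefficients"], f"survival_coefficients_{name}.csv")
            for key, frame in surv_reports[name]["curves"].items():
                safe = key.replace("|", "_").replace("+", "_")
                frame.to_csv(outdir / f"survival_curves_{name}_{safe}.csv")
                written.append(outdir / f"survival_curves_{name}_{safe}.csv")

        stage = "manifest"
        manifest = {
            "master_seed": config.master_seed,
            "cohorts": {s.name: {"n": s.n, "seed": s.seed} for s in config.cohort_specs},
            "outputs": {p.name: _sha256(p) for p in sorted(written)},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "tables": by_name,
        "test": test,
        "scored": scored,
        "federated_params": fed_params,
        "local_params": local_params,
        "round_log": fed_log,
        "mae_grid": mae_grid,
        "bias": pd.DataFrame(bias_rows),
        "corrections": corrections,
        "associations": ladders,
        "survival": surv_reports,
        "manifest": manifest,
    }
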