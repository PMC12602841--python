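"""Cox proportional-hazards profiling of the age-gap scores.

The hazard model is lambda(t | MAG, BAG, X) = lambda_0(t) * exp(beta_1*MAG +
beta_2*BAG + sum_i beta_i x_i), fit by partial-likelihood maximization with
Breslow tie handling and the Breslow baseline cumulative hazard. The gap
scores enter uncorrected for age bias because chronological age is always a
covariate. Survival curves are predicted at the four covariate profiles formed
by crossing the 1st/3rd empirical quartiles of BAG and MAG (other covariates
held at mean for continuous, mode for binary/categorical).

Model fitting is delegated to :class:`lifelines.CoxPHFitter`; an explicit
numpy implementation of the Breslow negative log partial likelihood and its
gradient is kept alongside as an independent check (gradient norm at the
optimum, brute-force grid maximization on toy instances).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

COX_COVARIATE_SETS: dict[str, list[str]] = {
    "age_only": ["age"],
    "full": ["age", "sex", "dm", "lag_time", "bmi", "ec1", "ec3"],
}


def compute_gaps(table: pd.DataFrame) -> pd.DataFrame:
    """Add bag/mag columns: predicted score minus chronological age (years).

    No bias correction is applied; age is adjusted for downstream instead.
    """
    for col in ("brainage", "metaboage"):
        if col not in table.columns:
            raise KeyError(f"missing score column {col!r}")
    out = table.copy()
    out["bag"] = out["brainage"] - out["age"]
    out["mag"] = out["metaboage"] - out["age"]
    return out


@dataclass
class CoxFit:
    coefficients: pd.Series  # per-unit log hazard ratios
    ses: pd.Series
    pvalues: pd.Series
    baseline_cumhaz: pd.Series  # Breslow step function over event times
    n: int
    events: int
    dropped: tuple[str, ...]  # constant covariates (cancel in the partial likelihood)
    covariate_set: str
    duration_col: str
    event_col: str
    fitter: CoxPHFitter

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coefficients)


def fit_cox(
    records: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    covariate_set: str = "custom",
) -> CoxFit:
    """Maximize the Cox partial likelihood (Newton iterations, Breslow ties).

    SEs come from the inverse observed information; the baseline cumulative
    hazard is the Breslow estimator.
    """
    df = records[[duration_col, event_col, *covariates]].dropna()
    if len(df) == 0:
        raise ValueError("no complete records for the Cox fit")
    # a covariate constant within the sample cancels out of the partial
    # likelihood; drop it rather than letting Newton iterations blow up
    dropped = tuple(c for c in covariates if df[c].nunique() <= 1)
    covariates = [c for c in covariates if c not in dropped]
    if not covariates:
        raise ValueError("no non-constant covariates left to fit")
    df = df[[duration_col, event_col, *covariates]]
    times = df[duration_col].to_numpy(dtype=float)
    events = df[event_col].to_numpy(dtype=float)
    if np.any(times <= 0):
        raise ValueError("survival times must be strictly positive")
    n_events = int(events.sum())
    if n_events < 1:
        raise ValueError("no events; the partial likelihood is flat")
    cph = CoxPHFitter(baseline_estimation_method="breslow")
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # small-sample variance hints from the fitter
            cph.fit(df, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        beta = getattr(cph, "params_", None)
        grad_info = ""
        if beta is not None:
            g, _ = partial_likelihood_gradient(
                beta.to_numpy(), times, events, df[covariates].to_numpy(dtype=float)
            )
            grad_info = f" (last gradient norm {np.linalg.norm(g):.3g})"
        raise RuntimeError(f"Cox fit failed to converge{grad_info}") from exc
    # polish the solution with exact Newton steps so the partial-likelihood
    # gradient vanishes to tighter precision than the fitter's stopping rule
    Xmat = df[covariates].to_numpy(dtype=float)
    beta = cph.params_.loc[covariates].to_numpy().copy()
    for _ in range(25):
        _, grad, hess = _nll_grad_hess(beta, times, events, Xmat)
        if np.linalg.norm(grad) < 1e-10:
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta - step
    if np.all(np.isfinite(beta)):
        cph.params_.loc[covariates] = beta
    # lifelines' stored baseline is centered at the covariate means; rescale to
    # the covariates-at-zero Breslow baseline so S(t) = exp(-L0(t) e^{x beta})
    mean_lp = float(df[covariates].mean() @ cph.params_.loc[covariates])
    baseline = cph.baseline_cumulative_hazard_["baseline cumulative hazard"] * np.exp(-mean_lp)
    return CoxFit(
        coefficients=cph.params_.copy(),
        ses=cph.standard_errors_.copy(),
        pvalues=cph.summary["p"].copy(),
        baseline_cumhaz=baseline,
        n=len(df),
        events=n_events,
        dropped=dropped,
        covariate_set=covariate_set,
        duration_col=duration_col,
        event_col=event_col,
        fitter=cph,
    )


def neg_log_partial_likelihood(
    beta: np.ndarray, times: np.ndarray, events: np.ndarray, X: np.ndarray
) -> float:
    """Breslow negative log partial likelihood (independent oracle path)."""
    nll, _ = _nll_and_grad(beta, times, events, X)
    return nll


def partial_likelihood_gradient(
    beta: np.ndarray, times: np.ndarray, events: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, float]:
    """Gradient of the Breslow negative log partial likelihood, plus its value."""
    nll, grad = _nll_and_grad(beta, times, events, X)
    return grad, nll


def _nll_grad_hess(beta, times, events, X):
    """Value, gradient and observed information of the Breslow nll."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != times.shape[0]:
        X = X.T
    order = np.argsort(-times, kind="stable")
    t, e, Xs = times[order], events[order], X[order]
    xb = Xs @ beta
    w = np.exp(xb)
    cum_w = np.cumsum(w)
    cum_wx = np.cumsum(w[:, None] * Xs, axis=0)
    outer = w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :])
    cum_wxx = np.cumsum(outer, axis=0)
    last_of_group = np.r_[t[1:] != t[:-1], True]
    boundaries = np.flatnonzero(last_of_group)
    group_end = boundaries[np.searchsorted(boundaries, np.arange(t.size))]
    ev = e > 0
    s0 = cum_w[group_end][ev]
    s1 = cum_wx[group_end][ev]
    s2 = cum_wxx[group_end][ev]
    nll = -float(np.sum(xb[ev] - np.log(s0)))
    mean_x = s1 / s0[:, None]
    grad = -(Xs[ev].sum(axis=0) - mean_x.sum(axis=0))
    hess = (s2 / s0[:, None, None] - mean_x[:, :, None] * mean_x[:, None, :]).sum(axis=0)
    return nll, grad, hess


def _nll_and_grad(beta, times, events, X):
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != times.shape[0]:
        X = X.T
    order = np.argsort(-times, kind="stable")  # descending: prefix = risk set
    t, e, Xs = times[order], events[order], X[order]
    xb = Xs @ beta
    w = np.exp(xb)
    cum_w = np.cumsum(w)
    cum_wx = np.cumsum(w[:, None] * Xs, axis=0)
    # for tied times the risk set is everyone with time >= t: map each row to
    # the last index of its descending-time group
    last_of_group = np.r_[t[1:] != t[:-1], True]
    boundaries = np.flatnonzero(last_of_group)
    group_end = boundaries[np.searchsorted(boundaries, np.arange(t.size))]
    ev = e > 0
    denom_w = cum_w[group_end][ev]
    denom_wx = cum_wx[group_end][ev]
    nll = -float(np.sum(xb[ev] - np.log(denom_w)))
    grad = -(Xs[ev].sum(axis=0) - (denom_wx / denom_w[:, None]).sum(axis=0))
    return nll, grad


@dataclass(frozen=True)
class QuartileProfile:
    """One of the four BAG-by-MAG quartile covariate profiles."""

    bag_level: str  # Q1 | Q3
    mag_level: str
    row: dict  # full covariate row at which to predict

    @property
    def label(self) -> str:
        return f"BAG {self.bag_level} / MAG {self.mag_level}"


def quartile_profiles(
    table: pd.DataFrame,
    score_cols: tuple[str, str] = ("bag", "mag"),
    covariates: list[str] | None = None,
) -> list[QuartileProfile]:
    """The four profiles crossing each score's empirical 25th/75th percentile.

    Quantiles use the linear-interpolation convention. Remaining covariates
    are fixed at the mean (continuous) or mode (binary/categorical).
    """
    s1, s2 = score_cols
    q = {
        c: (
            float(np.quantile(table[c].to_numpy(dtype=float), 0.25)),
            float(np.quantile(table[c].to_numpy(dtype=float), 0.75)),
        )
        for c in (s1, s2)
    }
    for c in (s1, s2):
        if not q[c][0] < q[c][1]:
            raise ValueError(f"degenerate quartiles for {c!r}")
    base = {}
    for c in covariates or []:
        x = table[c]
        if x.nunique() <= 3:  # binary / dummy covariates at the mode
            base[c] = float(x.mode().iloc[0])
        else:
            base[c] = float(x.mean())
    profiles = []
    for lvl1, v1 in zip(("Q1", "Q3"), q[s1]):
        for lvl2, v2 in zip(("Q1", "Q3"), q[s2]):
            row = dict(base)
            row[s1] = v1
            row[s2] = v2
            profiles.append(QuartileProfile(bag_level=lvl1, mag_level=lvl2, row=row))
    return profiles


def predicted_survival(fit: CoxFit, profile: QuartileProfile) -> pd.Series:
    """S(t) = exp(-Lambda_0(t) * exp(linear predictor at the profile))."""
    needed = set(fit.coefficients.index)
    if needed != set(profile.row):
        raise ValueError(
            f"profile covariates {sorted(profile.row)} do not match fit covariates {sorted(needed)}"
        )
    X = pd.DataFrame([profile.row])
    surv = fit.fitter.predict_survival_function(X)
    s = surv.iloc[:, 0]
    s.name = profile.label
    return s


def run_survival_suite(
    table: pd.DataFrame,
    outcomes: tuple[str, ...] = ("mortality", "dementia"),
    score_pairs: tuple[tuple[str, str], ...] = (("bag", "mag"), ("bag", "metabohealth")),
    covariate_sets: tuple[str, ...] = ("age_only", "full"),
) -> dict:
    """Separate and pairwise Cox fits per outcome, plus quartile-profile curves.

    Returns ``{"coefficients": tidy DataFrame, "curves": {key: DataFrame},
    "skipped": [...]}``. Outcomes whose columns are absent or all-missing are
    skipped with a note rather than failing (a cohort may simply not collect
    long-term follow-up).
    """
    outcome_cols = {"mortality": ("time_mort", "event_mort"), "dementia": ("time_dem", "event_dem")}
    coef_rows, curves, skipped = [], {}, []
    for outcome in outcomes:
        tcol, ecol = outcome_cols[outcome]
        if tcol not in table.columns or table[ecol].dropna().empty:
            skipped.append(f"{outcome}: outcome columns absent or empty; skipped")
            continue
        data = table.dropna(subset=[tcol, ecol])
        for cset in covariate_sets:
            covs = COX_COVARIATE_SETS[cset]
            for pair in score_pairs:
                model_specs = [(f"separate:{pair[0]}", [pair[0]]), (f"separate:{pair[1]}", [pair[1]]), (f"pairwise:{'+'.join(pair)}", list(pair))]
                for label, scores in model_specs:
                    try:
                        fit = fit_cox(data, tcol, ecol, scores + covs, covariate_set=cset)
                    except (RuntimeError, ValueError) as exc:
                        # small cohorts can separate on sparse covariates;
                        # record and move on rather than aborting the suite
                        skipped.append(f"{outcome}|{cset}|{label}: {exc}")
                        continue
                    for term in fit.coefficients.index:
                        coef_rows.append(
                            {
                                "outcome": outcome,
                                "covariate_set": cset,
                                "model": label,
                                "term": term,
                                "beta": fit.coefficients[term],
                                "hr": float(np.exp(fit.coefficients[term])),
                                "se": fit.ses[term],
                                "p": fit.pvalues[term],
                                "n": fit.n,
                                "events": fit.events,
                            }
                        )
                    if label.startswith("pairwise"):
                        fitted_covs = [c for c in covs if c not in fit.dropped]
                        profiles = quartile_profiles(data, (pair[0], pair[1]), fitted_covs)
                        frame = {}
                        for prof in profiles:
                            frame[prof.label] = predicted_survival(fit, prof)
                        curves[f"{outcome}|{cset}|{'+'.join(pair)}"] = pd.DataFrame(frame)
    return {"coefficients": pd.DataFrame(coef_rows), "curves": curves, "skipped": skipped}
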