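"""Federated linear-regression association analysis.

Models the association between the trainable imaging-based age score
(``brainage``) and a metabolomics response (``metaboage`` or ``metabohealth``)
across cohorts without pooling rows:

* variables are standardized with *federated* statistics — exact pooled
  means/SDs assembled from per-cohort sums, sums of squares and counts;
* each round every cohort takes one full-batch gradient-descent step on its
  standardized data, beta_l = beta_g - eta * (2/n) X'(X beta_g - y), and the
  server re-aggregates with the sample-size-weighted average
  beta_g = sum_j n_j beta_l_j / sum_j n_j;
* iteration stops when the pooled MAE stops changing; the whole procedure is
  restarted from several random initializations and the lowest-MAE model wins;
* an exact closed-form pooled OLS built from the same per-cohort sufficient
  statistics (X'X, X'y) serves as the oracle the gradient path must agree
  with, and supplies standard errors and t-test p-values.

Six nested covariate sets (M1..M6) mirror a covariate ladder from no
adjustment up to age, sex, diabetes, lag time, BMI and education (one-hot
relative to the medium level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

COVARIATE_SETS: dict[str, list[str]] = {
    "M1": [],
    "M2": ["age"],
    "M3": ["sex", "dm", "lag_time"],
    "M4": ["age", "sex", "dm", "lag_time"],
    "M5": ["sex", "dm", "lag_time", "bmi", "ec1", "ec3"],
    "M6": ["age", "sex", "dm", "lag_time", "bmi", "ec1", "ec3"],
}


@dataclass(frozen=True)
class AssociationSpec:
    response: str = "metaboage"  # metaboage | metabohealth
    covariate_set: str = "M2"  # key into COVARIATE_SETS or explicit list
    eta: float = 0.1
    max_rounds: int = 20000
    tol: float = 1e-8
    restarts: int = 10
    seed: int = 0

    def covariates(self) -> list[str]:
        if isinstance(self.covariate_set, str):
            return COVARIATE_SETS[self.covariate_set]
        return list(self.covariate_set)

    def validate(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")


@dataclass(frozen=True)
class StandardizationStats:
    """Exact pooled mean/SD per variable from per-cohort sufficient statistics."""

    means: dict[str, float]
    sds: dict[str, float]
    n_total: int

    def standardize(self, values: np.ndarray, var: str) -> np.ndarray:
        return (values - self.means[var]) / self.sds[var]


@dataclass
class AssociationResult:
    betas: pd.Series
    ses: pd.Series
    pvalues: pd.Series
    mae: float
    rounds_used: int = 0
    restart_index: int = 0
    degenerate: bool = False

    def to_row(self) -> dict:
        out = {f"beta_{t}": v for t, v in self.betas.items()}
        out.update({f"se_{t}": v for t, v in self.ses.items()})
        out.update({f"p_{t}": v for t, v in self.pvalues.items()})
        out["mae"] = self.mae
        out["rounds_used"] = self.rounds_used
        return out


def add_dummies(table: pd.DataFrame) -> pd.DataFrame:
    """Add ec1/ec3 one-hot columns (low/high education relative to medium)."""
    out = table.copy()
    out["ec1"] = (out["ec"] == "low").astype(float)
    out["ec3"] = (out["ec"] == "high").astype(float)
    return out


def federated_standardize(tables: list[pd.DataFrame], variables: list[str]) -> StandardizationStats:
    """Pooled mean/SD per variable from per-cohort (sum, sum of squares, n).

    Equals the centralized computation on the concatenated table to machine
    precision (sample SD, ddof = 1). Raises if any variable has zero pooled
    variance, naming it.
    """
    n_total = 0
    sums = {v: 0.0 for v in variables}
    sqs = {v: 0.0 for v in variables}
    for t in tables:
        missing = [v for v in variables if v not in t.columns]
        if missing:
            raise KeyError(f"variables missing from a cohort table: {missing}")
        n_total += len(t)
        for v in variables:
            x = t[v].to_numpy(dtype=float)
            sums[v] += float(x.sum())
            sqs[v] += float((x * x).sum())
    if n_total < 2:
        raise ValueError("need at least 2 pooled rows to standardize")
    means = {v: sums[v] / n_total for v in variables}
    sds = {}
    for v in variables:
        var = (sqs[v] - n_total * means[v] ** 2) / (n_total - 1)
        if var <= 0:
            raise ValueError(f"variable {v!r} has zero pooled variance; cannot standardize")
        sds[v] = float(np.sqrt(var))
    return StandardizationStats(means, sds, n_total)


def _design(
    table: pd.DataFrame, spec: AssociationSpec, stats: StandardizationStats
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Standardized design matrix (with intercept column) and response."""
    t = add_dummies(table) if ("ec1" in _needed_dummies(spec)) else table
    terms = ["intercept", "brainage", *spec.covariates()]
    n = len(t)
    X = np.empty((n, len(terms)))
    X[:, 0] = 1.0
    for j, term in enumerate(terms[1:], start=1):
        X[:, j] = stats.standardize(t[term].to_numpy(dtype=float), term)
    y = stats.standardize(t[spec.response].to_numpy(dtype=float), spec.response)
    return X, y, terms


def _needed_dummies(spec: AssociationSpec) -> set[str]:
    return {c for c in spec.covariates() if c in ("ec1", "ec3")}


def standardization_for(tables: list[pd.DataFrame], spec: AssociationSpec) -> StandardizationStats:
    """Federated standardization of every variable the spec's model touches."""
    variables = [spec.response, "brainage", *spec.covariates()]
    prepped = [add_dummies(t) if _needed_dummies(spec) else t for t in tables]
    return federated_standardize(prepped, variables)


def _sufficient_stats(tables, spec, stats):
    """Per-cohort X'X, X'y, y'y, n — the only quantities cohorts would share.

    Also returns the per-cohort (X, y) designs so the pooled-MAE stopping rule
    does not rebuild them every round.
    """
    out, designs = [], []
    terms = None
    for t in tables:
        X, y, terms = _design(t, spec, stats)
        out.append((X.T @ X, X.T @ y, float(y @ y), len(y)))
        designs.append((X, y))
    return out, terms, designs


def _pooled_mae(designs, beta) -> float:
    total, n = 0.0, 0
    for X, y in designs:
        total += float(np.abs(X @ beta - y).sum())
        n += len(y)
    return total / n


def _se_p_from_stats(suff, beta):
    """Standard errors and two-sided t p-values from pooled sufficient stats."""
    XtX = sum(s[0] for s in suff)
    Xty = sum(s[1] for s in suff)
    yty = sum(s[2] for s in suff)
    n = sum(s[3] for s in suff)
    p = beta.size
    rss = max(yty - 2 * beta @ Xty + beta @ XtX @ beta, 0.0)
    dof = n - p
    degenerate = dof <= 0 or rss <= 1e-12 * max(yty, 1.0)
    if degenerate:
        se = np.zeros(p)
        pvals = np.full(p, np.nan)
    else:
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(XtX)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta / se, np.inf)
        pvals = 2 * sps.t.sf(np.abs(tstat), dof)
    return se, pvals, degenerate


def closed_form_pooled_ols(
    tables: list[pd.DataFrame], spec: AssociationSpec, stats: StandardizationStats | None = None
) -> AssociationResult:
    """Exact pooled OLS from per-cohort sufficient statistics.

    beta = (X'X)^-1 X'y with X'X, X'y accumulated over cohorts — identical to
    OLS on the concatenated table. This is the oracle the federated gradient
    path is checked against, and the source of SEs and p-values.
    """
    spec.validate()
    if stats is None:
        stats = standardization_for(tables, spec)
    suff, terms, designs = _sufficient_stats(tables, spec, stats)
    XtX = sum(s[0] for s in suff)
    Xty = sum(s[1] for s in suff)
    rank = np.linalg.matrix_rank(XtX)
    if rank < XtX.shape[0]:
        # identify columns involved in the dependency via tiny QR pivots
        _, R = np.linalg.qr(XtX)
        bad = [terms[j] for j in range(len(terms)) if abs(R[j, j]) < 1e-8 * abs(R[0, 0])]
        raise np.linalg.LinAlgError(f"singular design; collinear columns: {bad}")
    beta = np.linalg.solve(XtX, Xty)
    se, pvals, degenerate = _se_p_from_stats(suff, beta)
    return AssociationResult(
        betas=pd.Series(beta, index=terms),
        ses=pd.Series(se, index=terms),
        pvalues=pd.Series(pvals, index=terms),
        mae=_pooled_mae(designs, beta),
        degenerate=degenerate,
    )


def federated_linreg(
    tables: list[pd.DataFrame], spec: AssociationSpec, stats: StandardizationStats | None = None
) -> AssociationResult:
    """Federated gradient-descent fit of the association model.

    Each round every cohort takes one gradient step from the shared
    coefficients and the server re-aggregates with the n-weighted average;
    iteration stops when the pooled MAE changes by less than ``spec.tol``.
    The procedure restarts ``spec.restarts`` times from small random
    initializations and keeps the lowest-MAE model. SEs and p-values come
    from the closed-form sufficient-statistic path.
    """
    spec.validate()
    if stats is None:
        stats = standardization_for(tables, spec)
    suff, terms, designs = _sufficient_stats(tables, spec, stats)
    sizes = np.array([s[3] for s in suff], dtype=float)
    n_total = sizes.sum()
    p = len(terms)

    best = None
    for r in range(spec.restarts):
        rng = np.random.default_rng([spec.seed, r])
        beta = rng.normal(0.0, 0.01, size=p)
        prev_mae = None
        rounds = 0
        for rounds in range(1, spec.max_rounds + 1):
            local = []
            for XtX, Xty, _, n_j in suff:
                grad = (2.0 / n_j) * (XtX @ beta - Xty)
                local.append(beta - spec.eta * grad)
            beta = np.asarray(local).T @ sizes / n_total
            if not np.all(np.isfinite(beta)):
                raise FloatingPointError(
                    f"federated regression diverged at round {rounds}; try a smaller eta"
                )
            cur_mae = _pooled_mae(designs, beta)
            if prev_mae is not None and abs(cur_mae - prev_mae) < spec.tol:
                break
            prev_mae = cur_mae
        final_mae = _pooled_mae(designs, beta)
        if best is None or final_mae < best[0]:
            best = (final_mae, beta, rounds, r)

    final_mae, beta, rounds, restart = best
    se, pvals, degenerate = _se_p_from_stats(suff, beta)
    return AssociationResult(
        betas=pd.Series(beta, index=terms),
        ses=pd.Series(se, index=terms),
        pvalues=pd.Series(pvals, index=terms),
        mae=final_mae,
        rounds_used=rounds,
        restart_index=restart,
        degenerate=degenerate,
    )


def run_covariate_ladder(
    tables: list[pd.DataFrame],
    response: str = "metaboage",
    method: str = "federated",
    model_ids: tuple[str, ...] = ("M1", "M2", "M3", "M4", "M5", "M6"),
    seed: int = 0,
    **spec_kwargs,
) -> dict[str, AssociationResult]:
    """Fit the six-model covariate ladder; one AssociationResult per model id."""
    fit = federated_linreg if method == "federated" else closed_form_pooled_ols
    results = {}
    for mid in model_ids:
        spec = AssociationSpec(response=response, covariate_set=mid, seed=seed, **spec_kwargs)
        results[mid] = fit(tables, spec)
    return results


def _marker(p: float) -> str:
    if not np.isfinite(p):
        return "?"
    if p <= 5e-10:
        return "**"
    if p <= 0.05:
        return "*"
    return "="


def ladder_table(results: dict[str, AssociationResult]) -> pd.DataFrame:
    """Wide summary: one row per model, beta (with significance marker) per
    term, final MAE last. Markers: ** p<=5e-10, * p<=0.05, = otherwise."""
    all_terms: list[str] = []
    for res in results.values():
        for t in res.betas.index:
            if t != "intercept" and t not in all_terms:
                all_terms.append(t)
    rows = []
    for mid, res in results.items():
        row: dict = {"model": mid}
        for t in all_terms:
            if t in res.betas.index:
                row[t] = f"{res.betas[t]:.2f}{_marker(res.pvalues[t])}"
            else:
                row[t] = "-"
        row["mae"] = round(res.mae, 2)
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")


def tidy_results(results: dict[str, AssociationResult]) -> pd.DataFrame:
    """Long-format results: model, term, beta, se, p, mae, rounds."""
    rows = []
    for mid, res in results.items():
        for t in res.betas.index:
            rows.append(
                {
                    "model": mid,
                    "term": t,
                    "beta": res.betas[t],
                    "se": res.ses[t],
                    "p": res.pvalues[t],
                    "mae": res.mae,
                    "rounds_used": res.rounds_used,
                }
            )
    return pd.DataFrame(rows)
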