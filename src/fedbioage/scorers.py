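"""Fixed-coefficient metabolomics scorers.

Two linear scorers over the 56-metabolite NMR-style panel:

* an age scorer (``output_kind="age_years"``): intercept + weighted sum of all
  56 metabolites, read out in years — the MetaboAge pattern;
* a mortality scorer (``output_kind="mortality_score"``): a weighted sum of a
  14-metabolite subset, z-standardized within the scored table — the
  MetaboHealth pattern.

The published coefficient values are not reproduced here; synthetic stand-in
coefficients are derived from the generator's own truth so that, on noise-free
data, the age scorer returns exactly ``age + metab_gap``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohorts import METAB_COLS, GeneratorTruth

N_AGE_PANEL = 56
N_MORTALITY_PANEL = 14


@dataclass(frozen=True)
class ScorerCoefficients:
    """A named linear scorer over metabolite columns."""

    intercept: float
    weights: dict[str, float]  # metabolite column -> weight
    output_kind: str  # age_years | mortality_score

    def validate(self) -> None:
        expected = {"age_years": N_AGE_PANEL, "mortality_score": N_MORTALITY_PANEL}
        if self.output_kind not in expected:
            raise ValueError(f"unknown output_kind {self.output_kind!r}")
        if len(self.weights) != expected[self.output_kind]:
            raise ValueError(
                f"{self.output_kind} scorer needs {expected[self.output_kind]} weights, "
                f"got {len(self.weights)}"
            )
        vals = np.array(list(self.weights.values()) + [self.intercept])
        if not np.all(np.isfinite(vals)):
            raise ValueError("scorer coefficients must be finite")


def score_metabolite_model(coeffs: ScorerCoefficients, table: pd.DataFrame) -> np.ndarray:
    """Apply a linear metabolite scorer row-wise.

    The age scorer returns years; the mortality scorer returns the linear
    predictor z-standardized over the input table (a within-table convention
    that puts it on a scale comparable to the age-gap scores).
    """
    coeffs.validate()
    missing = [m for m in coeffs.weights if m not in table.columns]
    if missing:
        raise KeyError(f"missing metabolite columns: {missing}")
    cols = list(coeffs.weights)
    w = np.array([coeffs.weights[c] for c in cols])
    score = coeffs.intercept + table[cols].to_numpy(dtype=float) @ w
    if coeffs.output_kind == "mortality_score":
        sd = score.std(ddof=1) if score.size > 1 else 0.0
        if sd == 0:
            return np.zeros_like(score)
        score = (score - score.mean()) / sd
    return score


def synthetic_metaboage_coefficients(truth: GeneratorTruth) -> ScorerCoefficients:
    """Synthetic age-scorer weights: the pseudo-inverse of the generator map.

    Since metabolites = w_metab * (age + metab_gap) + noise, the row
    pseudo-inverse w / ||w||^2 recovers (age + metab_gap) exactly in the
    noise-free case and with attenuating noise otherwise — a synthetic
    stand-in for the published 56-metabolite age model.
    """
    w = truth.w_metab
    pinv = w / float(w @ w)
    return ScorerCoefficients(
        intercept=0.0,
        weights=dict(zip(METAB_COLS, pinv.tolist())),
        output_kind="age_years",
    )


def synthetic_metabohealth_coefficients(
    truth: GeneratorTruth, n_panel: int = N_MORTALITY_PANEL
) -> ScorerCoefficients:
    """Synthetic mortality-scorer weights on a 14-metabolite sub-panel.

    Uses the ``n_panel`` metabolites with the largest generator loadings,
    weighted by their pseudo-inverse entries, so the score tracks the
    metabolic-aging signal (age + metab_gap) that drives mortality in the
    synthetic world. Stand-in for the published 14-metabolite mortality model.
    """
    w = truth.w_metab
    top = np.argsort(-np.abs(w))[:n_panel]
    sub = np.zeros_like(w)
    sub[top] = w[top] / float(w[top] @ w[top])
    weights = {METAB_COLS[j]: float(sub[j]) for j in top}
    return ScorerCoefficients(intercept=0.0, weights=weights, output_kind="mortality_score")


def write_scorer(coeffs: ScorerCoefficients, path) -> None:
    """Two-column delimited file (metabolite, weight) with header metadata lines."""
    with open(path, "w") as fh:
        fh.write(f"#output_kind\t{coeffs.output_kind}\n")
        fh.write(f"#intercept\t{coeffs.intercept!r}\n")
        for name, w in coeffs.weights.items():
            fh.write(f"{name}\t{w!r}\n")


def read_scorer(path) -> ScorerCoefficients:
    meta, weights = {}, {}
    with open(path) as fh:
        for line in fh:
            key, val = line.rstrip("\n").split("\t")
            if key.startswith("#"):
                meta[key[1:]] = val
            else:
                weights[key] = float(val)
    return ScorerCoefficients(
        intercept=float(meta["intercept"]), weights=weights, output_kind=meta["output_kind"]
    )
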