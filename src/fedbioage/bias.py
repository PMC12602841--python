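"""Linear age-bias correction for age predictors.

Age predictors systematically overestimate young participants and
underestimate old ones (regression toward the training mean). The standard
remedy regresses predicted age on chronological age in the *training* data,
pred = a*age + b, and removes the fitted bias. Two variants are provided:

``additive`` (default)
    corrected = pred + (age - (a*age + b)). Defined for any slope; on the fit
    set the corrected gap equals the OLS residual, hence is exactly
    uncorrelated with age.
``rescale``
    corrected = (pred - b) / a. The alternative family from the literature;
    undefined when a = 0.

Corrections are fit per training source (each local cohort and the federated
model) and the fit source is recorded so a correction is never silently fit
on evaluation data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class BiasCorrectionModel:
    slope: float  # a, unitless
    intercept: float  # b, years
    fit_source: str  # cohort name or "federated"
    fit_n: int
    variant: str = "additive"  # additive | rescale

    def validate(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("bias model coefficients must be finite")
        if self.fit_n < 2:
            raise ValueError("bias model must be fit on at least 2 points")
        if self.variant not in ("additive", "rescale"):
            raise ValueError(f"unknown variant {self.variant!r}")


def fit_bias_correction(
    pred: np.ndarray, age: np.ndarray, fit_source: str = "federated", variant: str = "additive"
) -> BiasCorrectionModel:
    """OLS fit of predicted age on chronological age (pred = a*age + b)."""
    pred = np.asarray(pred, dtype=float)
    age = np.asarray(age, dtype=float)
    if pred.shape != age.shape or pred.size < 2:
        raise ValueError("need equal-length vectors with at least 2 points")
    if np.ptp(age) == 0:
        raise ValueError("age is constant; bias slope is undefined")
    res = stats.linregress(age, pred)
    model = BiasCorrectionModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        fit_source=fit_source,
        fit_n=pred.size,
        variant=variant,
    )
    model.validate()
    return model


def apply_correction(model: BiasCorrectionModel, pred: np.ndarray, age: np.ndarray) -> np.ndarray:
    """Bias-corrected predicted ages (years)."""
    model.validate()
    pred = np.asarray(pred, dtype=float)
    age = np.asarray(age, dtype=float)
    if model.variant == "rescale":
        if model.slope == 0:
            raise ZeroDivisionError("rescale variant undefined for zero slope")
        return (pred - model.intercept) / model.slope
    return pred + (age - (model.slope * age + model.intercept))


def correction_report(
    model: BiasCorrectionModel, pred: np.ndarray, age: np.ndarray
) -> dict[str, float]:
    """Before/after MAE for one evaluation cohort (the generalization check)."""
    from .predictors import mae

    corrected = apply_correction(model, pred, age)
    return {
        "mae_before": mae(pred, age),
        "mae_after": mae(corrected, age),
        "slope": model.slope,
        "intercept": model.intercept,
    }


def write_bias_model(model: BiasCorrectionModel, path) -> None:
    """Persist as a single delimited record: source, n, a, b, variant."""
    with open(path, "w") as fh:
        fh.write("fit_source\tfit_n\tslope\tintercept\tvariant\n")
        fh.write(
            f"{model.fit_source}\t{model.fit_n}\t{model.slope!r}\t{model.intercept!r}\t{model.variant}\n"
        )


def read_bias_model(path) -> BiasCorrectionModel:
    with open(path) as fh:
        next(fh)
        src, n, a, b, variant = next(fh).rstrip("\n").split("\t")
    return BiasCorrectionModel(float(a), float(b), src, int(n), variant)
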