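"""BrainAGE: the brain-age gap, its linear bias correction, and the
group-level ANCOVA.

BrainAGE is predicted brain age minus chronological age (years).  Age
regressors systematically overestimate young and underestimate old
subjects, so the raw gap is corrected by fitting gap ~ alpha*age + beta
by ordinary least squares on a dedicated held-out correction cohort and
subtracting the fit everywhere (the offset-style correction).  The
corrected gap is then compared between clinical groups with an ANCOVA
controlled for age and sex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._glm import ancova

__all__ = [
    "BiasModel",
    "compute_brainage",
    "mae",
    "build_prediction_table",
    "fit_bias_correction",
    "apply_bias_correction",
    "ancova_brainage",
]


@dataclass(frozen=True)
class BiasModel:
    """gap ~ alpha * age + beta, fitted by OLS on the correction cohort."""

    alpha: float  # years of gap per year of age
    beta: float   # years
    fit_set_id: str = ""

    def __post_init__(self):
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError("bias coefficients must be finite")

    def predict(self, age: np.ndarray) -> np.ndarray:
        return self.alpha * np.asarray(age, dtype=float) + self.beta


def compute_brainage(predicted, age):
    """predicted brain age minus chronological age, in years."""
    predicted = np.asarray(predicted, dtype=float)
    age = np.asarray(age, dtype=float)
    if not (np.all(np.isfinite(predicted)) and np.all(np.isfinite(age))):
        raise ValueError("inputs must be finite")
    return predicted - age


def mae(predicted, age) -> float:
    """Mean absolute error between predicted and chronological age."""
    predicted = np.asarray(predicted, dtype=float)
    age = np.asarray(age, dtype=float)
    if predicted.shape != age.shape:
        raise ValueError("length mismatch")
    if predicted.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(predicted - age)))


def build_prediction_table(cohort: pd.DataFrame,
                           predicted: np.ndarray) -> pd.DataFrame:
    """Assemble a prediction table from a cohort and predicted ages."""
    predicted = np.asarray(predicted, dtype=float)
    if len(predicted) != len(cohort):
        raise ValueError("one prediction per cohort row required")
    out = cohort[["participant_id", "age", "sex", "group"]].copy()
    out["predicted_age"] = predicted
    out["gap_raw"] = compute_brainage(predicted, out["age"].to_numpy())
    return out


def fit_bias_correction(gaps, ages, fit_set_id: str = "") -> BiasModel:
    """OLS fit of gap on age: the Beheshti-style linear bias model."""
    gaps = np.asarray(gaps, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if gaps.shape != ages.shape or gaps.ndim != 1:
        raise ValueError("gaps and ages must be equal-length vectors")
    if len(gaps) < 3:
        raise ValueError("need at least 3 subjects to fit the bias")
    if np.var(ages) == 0:
        raise ValueError("age variance is zero; bias slope is unidentifiable")
    alpha, beta = np.polyfit(ages, gaps, 1)
    return BiasModel(alpha=float(alpha), beta=float(beta), fit_set_id=fit_set_id)


def apply_bias_correction(table: pd.DataFrame, model: BiasModel) -> pd.DataFrame:
    """Add gap_corrected = gap_raw - (alpha*age + beta) to the table."""
    out = table.copy()
    out["gap_corrected"] = out["gap_raw"].to_numpy() - model.predict(
        out["age"].to_numpy())
    return out


_FACTOR_LABELS = {"condition": "Condition", "age": "Age", "sex": "Gender"}


def ancova_brainage(table: pd.DataFrame, covariates=("age", "sex"),
                    corrected: bool = True) -> pd.DataFrame:
    """ANCOVA of BrainAGE on clinical condition, controlled for age/sex.

    ``corrected`` selects the bias-corrected or raw gap column.  Returns
    one row per factor: ``factor, SS, df, F, p, np2``.
    """
    dv = "gap_corrected" if corrected else "gap_raw"
    if dv not in table.columns:
        raise ValueError(f"table has no {dv!r} column"
                         + (" (fit and apply the bias correction first)"
                            if corrected else ""))
    cov = {}
    for name in covariates:
        col = table[name].to_numpy()
        cov[name] = col
    res = ancova(table[dv].to_numpy(), table["group"].to_numpy(), cov)
    res = res.drop(columns="column")
    res["factor"] = res["factor"].map(lambda f: _FACTOR_LABELS.get(f, f))
    res["dv"] = dv
    return res[["dv", "factor", "SS", "df", "F", "p", "np2"]]
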