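"""Cohort statistics: transforms and standardized age regressions.

Per-ROI noise-corrected mean Ki values are strongly right-skewed, so the
analyses run on the signed cube root; WMH volumes are log-transformed.
The core models are ordinary multiple linear regressions of transformed
Ki on age and sex (optionally plus vascular confounders), reported as
standardized coefficients beta = b * SD(x) / SD(y), and two-stage
interaction models with one structural brain-integrity measure: the
age x measure interaction (both mean-centered) is fitted first and
pruned when non-significant, after which main effects are read from the
reduced model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "KI_COLUMNS", "INTEGRITY_MEASURES", "CONFOUNDERS", "RegressionResult",
    "transform_ki", "transform_wmh", "fit_age_model", "fit_interaction_model",
]

#: Per-ROI mean-Ki column names expected in a cohort table.
KI_COLUMNS = {
    "white_matter": "ki_white_matter",
    "gray_matter": "ki_gray_matter",
    "primary": "ki_primary",
    "secondary": "ki_secondary",
    "tertiary": "ki_tertiary",
}

#: Structural brain-integrity measures usable in interaction models.
INTEGRITY_MEASURES = ("wmh_volume", "cortical_thickness", "hippocampal_volume")

#: Vascular confounders added when ``confounders=True``.
CONFOUNDERS = ("sbp", "bmi", "diabetes", "smoker")

ALPHA = 0.05


@dataclass
class RegressionResult:
    """Standardized regression output for one ROI model.

    ``beta`` and ``p`` map predictor name -> standardized coefficient /
    two-sided p-value.  For interaction models, ``stage1_beta`` /
    ``stage1_p`` hold the full model including the interaction term and
    ``interaction_pruned`` records whether the reported main effects come
    from the reduced model.
    """

    roi: str
    predictors: list[str]
    beta: dict[str, float]
    p: dict[str, float]
    n: int
    interaction_pruned: bool | None = None
    stage1_beta: dict[str, float] | None = None
    stage1_p: dict[str, float] | None = None

    def significant(self, predictor: str, alpha: float = ALPHA) -> bool:
        return self.p[predictor] < alpha

    def to_frame(self) -> pd.DataFrame:
        rows = [{"roi": self.roi, "predictor": k, "beta": self.beta[k],
                 "p": self.p[k], "n": self.n, "model_stage": "final"}
                for k in self.predictors]
        if self.stage1_beta is not None:
            rows += [{"roi": self.roi, "predictor": k,
                      "beta": self.stage1_beta[k], "p": self.stage1_p[k],
                      "n": self.n, "model_stage": "with_interaction"}
                     for k in self.stage1_beta]
        return pd.DataFrame(rows)


def transform_ki(values: np.ndarray) -> np.ndarray:
    """Signed cube root, ``sign(x) |x|^(1/3)``.

    Strictly monotone and invertible; negative noise-corrected means map
    to negative transformed values rather than NaN.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("transform_ki requires finite values")
    return np.cbrt(values)


def transform_wmh(values: np.ndarray, offset: float | None = None) -> np.ndarray:
    """Natural log of WMH volume (cm^3).

    Non-positive volumes are rejected unless a small positive ``offset``
    is supplied, in which case ``log(max(v, 0) + offset)`` is used and a
    warning records how many values needed it.
    """
    values = np.asarray(values, dtype=float)
    if offset is None:
        if np.any(values <= 0):
            raise ValueError(
                "WMH volumes must be positive; pass offset=<small value> "
                "to handle zeros")
        return np.log(values)
    if offset <= 0:
        raise ValueError(f"offset must be positive, got {offset}")
    n_bad = int(np.sum(values <= 0))
    if n_bad:
        warnings.warn(f"{n_bad} non-positive WMH volumes offset by {offset}",
                      stacklevel=2)
    return np.log(np.clip(values, 0.0, None) + offset)


def _standardized_ols(y: np.ndarray, X: pd.DataFrame) -> tuple[dict, dict, int]:
    """OLS with intercept; returns standardized betas and p-values.

    beta_j = b_j * SD(x_j) / SD(y) with sample (ddof=1) standard
    deviations, the convention of common statistical packages; binary
    predictors are standardized identically.
    """
    for col in X.columns:
        if np.std(X[col].to_numpy()) == 0:
            raise ValueError(f"constant predictor: {col!r}")
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    sdy = np.std(y, ddof=1)
    beta = {c: float(model.params[c] * np.std(X[c].to_numpy(), ddof=1) / sdy)
            for c in X.columns}
    p = {c: float(model.pvalues[c]) for c in X.columns}
    return beta, p, int(model.nobs)


def _prepare(table: pd.DataFrame, roi: str, columns: list[str]) -> pd.DataFrame:
    ki_col = KI_COLUMNS.get(roi, roi)
    if ki_col not in table.columns:
        raise ValueError(f"cohort table lacks column {ki_col!r}")
    sub = table[[ki_col] + columns].copy()
    n0 = len(sub)
    sub = sub.dropna()
    if len(sub) < n0:
        warnings.warn(f"dropped {n0 - len(sub)} rows with missing data",
                      stacklevel=3)
    if len(sub) < 10:
        raise ValueError(f"need >= 10 complete rows, have {len(sub)}")
    return sub.rename(columns={ki_col: "_ki"})


def fit_age_model(
    table: pd.DataFrame,
    roi: str,
    confounders: bool = False,
) -> RegressionResult:
    """Regress cube-root-transformed mean Ki on age and sex.

    With ``confounders=True`` systolic blood pressure, BMI, diabetes and
    smoking enter as additional predictors.  Coefficients are
    standardized as b*SD(x)/SD(y); p-values are two-sided t-tests.
    """
    preds = ["age", "sex"] + (list(CONFOUNDERS) if confounders else [])
    sub = _prepare(table, roi, preds)
    y = transform_ki(sub["_ki"].to_numpy())
    beta, p, n = _standardized_ols(y, sub[preds])
    return RegressionResult(roi=roi, predictors=preds, beta=beta, p=p, n=n)


def fit_interaction_model(
    table: pd.DataFrame,
    roi: str,
    integrity_measure: str,
    alpha: float = ALPHA,
) -> RegressionResult:
    """Two-stage integrity-measure model with interaction pruning.

    Stage 1 regresses transformed Ki on age, sex, the chosen integrity
    measure and the age x measure interaction (both factors mean-centered
    before multiplication).  When the interaction is not significant at
    ``alpha`` it is removed and the main effects are reported from the
    reduced stage-2 model; both stages are returned.
    """
    if integrity_measure not in INTEGRITY_MEASURES:
        raise ValueError(
            f"integrity_measure must be one of {INTEGRITY_MEASURES}, "
            f"got {integrity_measure!r}")
    sub = _prepare(table, roi, ["age", "sex", integrity_measure])
    measure = sub[integrity_measure].to_numpy(dtype=float)
    if integrity_measure == "wmh_volume":
        measure = transform_wmh(measure)
    y = transform_ki(sub["_ki"].to_numpy())
    age = sub["age"].to_numpy(dtype=float)
    X = pd.DataFrame({
        "age": age,
        "sex": sub["sex"].to_numpy(dtype=float),
        integrity_measure: measure,
        "age_x_measure": (age - age.mean()) * (measure - measure.mean()),
    }, index=sub.index)
    beta1, p1, n = _standardized_ols(y, X)
    pruned = p1["age_x_measure"] >= alpha
    if pruned:
        X2 = X.drop(columns="age_x_measure")
        beta, p, n = _standardized_ols(y, X2)
        preds = list(X2.columns)
    else:
        beta, p, preds = beta1, p1, list(X.columns)
    return RegressionResult(roi=roi, predictors=preds, beta=beta, p=p, n=n,
                            interaction_pruned=bool(pruned),
                            stage1_beta=beta1, stage1_p=p1)
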