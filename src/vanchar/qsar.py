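"""Multiple-linear-regression QSAR: fit, diagnostics and prediction.

The model links four molecular descriptors — total polar surface area
(ASA_P, Å²), total hydrophobic surface area (ASA_H, Å²), the pK_b of
protonation at pH 7 (h_pkp) and the dipole moment (Debye) — linearly to
a biological activity (IC50, µM):

    Y = b1·ASA_P + b2·ASA_H + b3·h_pkp + b4·dipole + C.

Fitting is ordinary least squares with intercept (statsmodels under the
hood); diagnostics report R (Pearson correlation of fitted vs observed),
R², per-record residuals and a leave-one-out q².  The activity may be
regressed directly (the default) or on a log10 scale, in which case
predictions are transformed back to µM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "QsarError",
    "RankDeficiencyError",
    "DESCRIPTOR_COLUMNS",
    "QsarModel",
    "ValidationReport",
    "fit_mlr",
    "predict",
    "validate",
]

DESCRIPTOR_COLUMNS = ("ASA_P", "ASA_H", "h_pkp", "dipole")
#: Alternate header spellings accepted on input.
COLUMN_ALIASES = {"h_pkb": "h_pkp", "h_pKb": "h_pkp", "h_pK_b": "h_pkp"}


class QsarError(ValueError):
    """Raised for unusable descriptor/activity tables."""


class RankDeficiencyError(QsarError):
    """Raised when the descriptor matrix is rank deficient."""


def normalize_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with alias descriptor headers renamed canonically."""
    return table.rename(columns=COLUMN_ALIASES)


@dataclass
class QsarModel:
    """A fitted MLR QSAR model."""

    coefficients: dict[str, float]
    intercept: float
    r: float
    r_squared: float
    residuals: pd.Series
    fitted: pd.Series
    descriptors: tuple[str, ...]
    response: str
    response_transform: str          # "none" | "log10"
    degenerate: bool = False         # constant response, R undefined

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "r": None if self.degenerate else self.r,
            "r_squared": None if self.degenerate else self.r_squared,
            "response_transform": self.response_transform,
            "degenerate": self.degenerate,
        }


@dataclass
class ValidationReport:
    r: float
    r_squared: float
    q_squared: float
    residual_table: pd.DataFrame     # observed, predicted, residual per record


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Name descriptor columns involved in a rank deficiency."""
    base_rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.values]))
    culprits = []
    for col in X.columns:
        reduced = X.drop(columns=[col])
        r = np.linalg.matrix_rank(
            np.column_stack([np.ones(len(X)), reduced.values])
        )
        if r == base_rank:  # dropping the column loses nothing
            culprits.append(col)
    return culprits or list(X.columns)


def _design(table: pd.DataFrame, descriptors: Sequence[str]) -> pd.DataFrame:
    missing = [c for c in descriptors if c not in table.columns]
    if missing:
        raise QsarError(f"missing descriptor column(s): {missing}")
    X = table.loc[:, list(descriptors)].astype(float)
    if X.isna().any().any():
        raise QsarError("descriptor values must not be missing for fitting")
    return X


def fit_mlr(
    training: pd.DataFrame,
    response: str = "IC50",
    descriptors: Sequence[str] = DESCRIPTOR_COLUMNS,
    response_transform: str = "none",
) -> QsarModel:
    """Fit the MLR model by ordinary least squares with intercept.

    Requires strictly more complete records than parameters and a
    full-rank descriptor matrix; a constant response is fitted as
    intercept-only and flagged ``degenerate`` (R undefined).
    """
    if response_transform not in ("none", "log10"):
        raise ValueError(f"unknown response transform {response_transform!r}")
    training = normalize_columns(training)
    X = _design(training, descriptors)
    if response not in training.columns:
        raise QsarError(f"missing response column {response!r}")
    y = training[response].astype(float)
    if y.isna().any():
        raise QsarError("response values must be present for every training record")
    n, p = X.shape
    if n <= p + 1:
        raise QsarError(f"need more than {p + 1} records to fit, got {n}")
    if response_transform == "log10":
        if (y <= 0).any():
            raise QsarError("log10 transform requires strictly positive activities")
        y = np.log10(y)

    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X.values])) < p + 1:
        raise RankDeficiencyError(
            "descriptor matrix is rank deficient; collinear column(s): "
            + ", ".join(_collinear_columns(X))
        )

    if float(np.std(y)) == 0.0:
        const = float(y.iloc[0])
        zeros = pd.Series(0.0, index=X.index)
        return QsarModel(
            coefficients={c: 0.0 for c in descriptors},
            intercept=const,
            r=float("nan"),
            r_squared=float("nan"),
            residuals=zeros,
            fitted=pd.Series(const, index=X.index),
            descriptors=tuple(descriptors),
            response=response,
            response_transform=response_transform,
            degenerate=True,
        )

    res = sm.OLS(y, sm.add_constant(X)).fit()
    fitted = res.fittedvalues
    r = float(np.corrcoef(fitted, y)[0, 1])
    return QsarModel(
        coefficients={c: float(res.params[c]) for c in descriptors},
        intercept=float(res.params["const"]),
        r=r,
        r_squared=float(res.rsquared),
        residuals=res.resid,
        fitted=fitted,
        descriptors=tuple(descriptors),
        response=response,
        response_transform=response_transform,
    )


def predict(model: QsarModel, table: pd.DataFrame) -> pd.Series:
    """Predicted activity per record, inverse-transformed to µM scale.

    Records with a missing descriptor yield NaN (they are rejected
    individually; the rest proceed).
    """
    table = normalize_columns(table)
    missing_cols = [c for c in model.descriptors if c not in table.columns]
    if missing_cols:
        raise QsarError(f"missing descriptor column(s): {missing_cols}")
    X = table.loc[:, list(model.descriptors)].astype(float)
    yhat = X.mul(pd.Series(model.coefficients)).sum(axis=1, skipna=False)
    yhat = yhat + model.intercept
    if model.response_transform == "log10":
        yhat = 10.0**yhat
    yhat.name = f"predicted_{model.response}"
    return yhat


def validate(model: QsarModel, training: pd.DataFrame) -> ValidationReport:
    """Recompute R/R² from scratch and add a leave-one-out q².

    q² = 1 − PRESS/TSS on the (possibly transformed) response scale; each
    record is predicted by a model refitted without it.
    """
    if model.degenerate:
        raise QsarError("cannot validate a degenerate (constant-response) model")
    training = normalize_columns(training).reset_index(drop=True)
    X = _design(training, model.descriptors)
    y = training[model.response].astype(float)
    if model.response_transform == "log10":
        y = np.log10(y)
    pred = predict(model, training)
    if model.response_transform == "log10":
        pred = np.log10(pred)
    resid = y - pred
    r = float(np.corrcoef(pred, y)[0, 1])
    r_squared = r * r

    press = 0.0
    for i in range(len(training)):
        sub = training.drop(index=i)
        m_i = fit_mlr(
            sub,
            response=model.response,
            descriptors=model.descriptors,
            response_transform=model.response_transform,
        )
        p_i = predict(m_i, training.iloc[[i]]).iloc[0]
        if model.response_transform == "log10":
            p_i = np.log10(p_i)
        press += float((y.iloc[i] - p_i) ** 2)
    tss = float(np.sum((y - y.mean()) ** 2))
    q_squared = 1.0 - press / tss if tss > 0 else float("nan")

    table = pd.DataFrame(
        {
            "compound_id": training.get("compound_id", pd.Series(range(len(y)))),
            "observed": y,
            "predicted": pred,
            "residual": resid,
        }
    )
    return ValidationReport(r, r_squared, q_squared, table)
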