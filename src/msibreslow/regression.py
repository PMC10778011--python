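"""Continuous analyses: Pearson correlation and the multivariate linear
model relating multispectral features to Breslow depth.

The multivariate model regresses histological thickness on the mean green,
red and infrared channel intensities plus circularity (ordinary least
squares with an intercept); its summary correlation is the Pearson r
between fitted and observed thickness, which equals sqrt(R^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import FitError, InputError

PREDICTORS = ("mean_G", "mean_R", "mean_IR", "circularity")


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D sequences of equal length")
    if len(x) < 3:
        raise InputError("at least 3 observations required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("zero variance: correlation undefined")
    result = stats.pearsonr(x, y)
    return float(result.statistic), float(result.pvalue)


@dataclass(frozen=True)
class ModelFit:
    coefficients: dict[str, float]  # intercept + one slope per predictor
    fitted: np.ndarray
    r_multivariate: float
    f_statistic: float
    p_value: float
    stderr: dict[str, float]
    n: int


def fit_multivariate(features: pd.DataFrame, breslow) -> ModelFit:
    """OLS of Breslow thickness on (mean_G, mean_R, mean_IR, circularity).

    Raises :class:`FitError` naming the collinear predictors when the design
    matrix is rank deficient.
    """
    missing = [c for c in PREDICTORS if c not in features.columns]
    if missing:
        raise InputError(f"features table lacks columns: {missing}")
    y = np.asarray(breslow, float)
    X = features.loc[:, list(PREDICTORS)].to_numpy(float)
    if len(y) != len(X):
        raise InputError("features and breslow must have equal lengths")
    if len(y) < len(PREDICTORS) + 2:
        raise InputError(
            f"at least {len(PREDICTORS) + 2} lesions required, got {len(y)}"
        )
    design = np.column_stack([np.ones(len(y)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the predictors loading on the null space of the design
        _, _, vt = np.linalg.svd(design)
        null_vec = np.abs(vt[-1][1:])
        cutoff = 1e-6 * max(null_vec.max(), 1e-300)
        culprits = [p for p, w in zip(PREDICTORS, null_vec) if w > cutoff]
        raise FitError(f"rank-deficient design; collinear predictors: {culprits}")

    model = sm.OLS(y, sm.add_constant(X)).fit()
    names = ("intercept",) + PREDICTORS
    coefficients = dict(zip(names, (float(b) for b in model.params)))
    stderr = dict(zip(names, (float(s) for s in model.bse)))
    return ModelFit(
        coefficients=coefficients,
        fitted=np.asarray(model.fittedvalues, float),
        r_multivariate=float(np.sqrt(max(model.rsquared, 0.0))),
        f_statistic=float(model.fvalue),
        p_value=float(model.f_pvalue),
        stderr=stderr,
        n=len(y),
    )
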