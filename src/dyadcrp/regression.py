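"""Multiple regression of parenting stress on SOM activity vectors.

The model is PSI_i ~ d1..d16: ordinary least squares of the mother's total
Parenting Stress Index on the 16 neuron distances of one plot family
(mother RP, child RP, or dyad CRP) for one HRV index.  Fit quality is
summarized by adjusted R², the overall F-test p-value, RMSE and MAE, plus
a ±1σ tolerance band on the residuals.

Each subject contributes one row per recorded day (same PSI on every row);
``unit="subject"`` averages a subject's activity vectors first, for a
strict one-row-per-mother design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "RegressionResult",
    "StressRegression",
    "fit_psi_model",
    "loso_metrics",
    "tolerance_band",
    "compare_models",
]

N_FEATURES = 16


@dataclass
class RegressionResult:
    """OLS fit summary for one PSI ~ activity-vector model."""

    label: str
    params: np.ndarray  # intercept followed by 16 coefficients
    adj_r2: float
    r2: float
    f_pvalue: float
    rmse: float
    mae: float
    sigma: float  # sample std of residuals (the ±1σ band half-width)
    n_obs: int
    fitted: np.ndarray
    residuals: np.ndarray

    @property
    def significant(self) -> bool:
        return self.f_pvalue < 0.05


class StressRegression(RegressorMixin, BaseEstimator):
    """OLS of PSI on 16 SOM activities, scikit-learn style.

    Fitted attributes: ``result_`` (:class:`RegressionResult`), ``coef_``,
    ``intercept_``.  ``fit`` raises when the design has fewer than 18
    observations or is rank-deficient, since the overall F test needs
    n > p + 1 with p = 16 predictors.
    """

    def __init__(self, label: str = "model"):
        self.label = label

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != N_FEATURES:
            raise ValueError(f"X must be (n, {N_FEATURES})")
        n = X.shape[0]
        if n < N_FEATURES + 2:
            raise ValueError(
                f"too few observations: n={n} < {N_FEATURES + 2} needed for the F test"
            )
        design = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("collinear design: rank below 17 (intercept + 16)")
        ols = sm.OLS(y, design).fit()
        resid = np.asarray(ols.resid)
        self.result_ = RegressionResult(
            label=self.label,
            params=np.asarray(ols.params),
            adj_r2=float(ols.rsquared_adj),
            r2=float(ols.rsquared),
            f_pvalue=float(ols.f_pvalue),
            rmse=float(np.sqrt(np.mean(resid**2))),
            mae=float(np.mean(np.abs(resid))),
            sigma=float(np.std(resid, ddof=1)),
            n_obs=n,
            fitted=np.asarray(ols.fittedvalues),
            residuals=resid,
        )
        self.intercept_ = float(ols.params[0])
        self.coef_ = np.asarray(ols.params[1:])
        self.n_features_in_ = N_FEATURES
        return self

    def predict(self, X):
        check_is_fitted(self, "result_")
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_


def fit_psi_model(
    activities: np.ndarray,
    psi: np.ndarray,
    label: str = "model",
    subject_ids: np.ndarray | None = None,
    unit: str = "day",
) -> RegressionResult:
    """Fit PSI ~ d1..d16 and return the summary.

    ``unit="day"`` (default): one row per day-plot, a subject's PSI repeated
    across their days.  ``unit="subject"``: average each subject's activity
    vectors into one row (requires ``subject_ids``).
    """
    X = np.asarray(activities, dtype=float)
    y = np.asarray(psi, dtype=float)
    if unit == "subject":
        if subject_ids is None:
            raise ValueError("unit='subject' requires subject_ids")
        df = pd.DataFrame(X)
        df["_sid"] = np.asarray(subject_ids)
        df["_psi"] = y
        agg = df.groupby("_sid", sort=True).mean()
        X = agg.drop(columns="_psi").to_numpy()
        y = agg["_psi"].to_numpy()
    elif unit != "day":
        raise ValueError("unit must be 'day' or 'subject'")
    return StressRegression(label=label).fit(X, y).result_


def loso_metrics(
    activities: np.ndarray, psi: np.ndarray, subject_ids: np.ndarray
) -> dict:
    """Leave-one-subject-out RMSE/MAE for PSI ~ d1..d16.

    Out-of-sample companion to the default in-sample metrics: each subject's
    rows are predicted by a model fitted on everyone else's rows.  Requires
    every training fold to keep at least 18 rows.
    """
    X = np.asarray(activities, dtype=float)
    y = np.asarray(psi, dtype=float)
    sids = np.asarray(subject_ids)
    preds = np.empty_like(y)
    for sid in np.unique(sids):
        hold = sids == sid
        model = StressRegression().fit(X[~hold], y[~hold])
        preds[hold] = model.predict(X[hold])
    resid = y - preds
    return {
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "mae": float(np.mean(np.abs(resid))),
        "predictions": preds,
    }


def tolerance_band(result: RegressionResult) -> tuple[np.ndarray, float]:
    """Flag observations whose residual lies within ±1σ; return flags and coverage.

    σ is the sample standard deviation of the residuals, so for roughly
    Gaussian residuals the coverage approaches the normal 68.3%.
    """
    r = result.residuals
    # a numerically perfect fit has sigma ~ machine eps; count those as inside
    inside = (np.abs(r) <= result.sigma) | np.isclose(r, 0.0, atol=1e-8)
    return inside, float(inside.mean())


def compare_models(results: list[RegressionResult]) -> pd.DataFrame:
    """Rank fitted models by RMSE (ties by MAE) and flag significance.

    Returns a table with one row per model, ranked best first; the single
    best-fit model carries ``best=True``.  Significance is the overall
    F-test at the 0.05 level.
    """
    if not results:
        raise ValueError("no models to compare")
    rows = [
        {
            "label": r.label,
            "n": r.n_obs,
            "adj_r2": r.adj_r2,
            "f_pvalue": r.f_pvalue,
            "rmse": r.rmse,
            "mae": r.mae,
            "significant": r.significant,
        }
        for r in results
    ]
    df = pd.DataFrame(rows).sort_values(
        ["rmse", "mae"], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["best"] = df["rank"] == 1
    return df
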