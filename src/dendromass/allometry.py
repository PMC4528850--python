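"""Schumacher-Hall allometric biomass model and its residual diagnostics.

The model is the classical log-linear allometry

    ln(w) = a + b * ln(dbh) + c * ln(ht) + e_i

fitted by ordinary least squares on the log scale.  Back-transformation is
plain exponentiation by default; the Baskerville lognormal bias correction
exp(s^2/2) is available opt-in.

Diagnostics cover the three standard OLS residual assumptions: normality
(Shapiro-Wilk), homoscedasticity (White's test on the predictors, their
squares and cross-products) and serial independence (Durbin-Watson over
record order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_white
from statsmodels.stats.stattools import durbin_watson

from .data import TreeDataset, extract_features
from .neighbors import PredictionSet


@dataclass(frozen=True)
class DiagnosticsReport:
    """Residual-assumption test statistics for a fitted allometric model."""

    shapiro_wilk_W: float
    shapiro_wilk_p: float
    white_LM: float
    white_p: float
    durbin_watson: float

    def __post_init__(self):
        assert 0.0 <= self.durbin_watson <= 4.0
        assert self.white_LM >= 0.0
        assert self.shapiro_wilk_W <= 1.0


class SchumacherHallRegressor(RegressorMixin, BaseEstimator):
    """OLS fit of ln(w) on {1, ln(dbh), ln(ht)}.

    Parameters
    ----------
    back_transform : bool, default True
        Return predictions on the original biomass scale (exponentiated);
        with False the log-scale prediction a + b·ln(dbh) + c·ln(ht) is
        returned.
    correction : {"none", "baskerville"}, default "none"
        Retransformation bias handling: "baskerville" multiplies
        back-transformed predictions by exp(s²/2) with s² the residual
        variance of the log-scale fit.

    Attributes (after fit)
    ----------------------
    a_, b_, c_ : float       intercept and the ln(dbh), ln(ht) coefficients
    residuals_ : ndarray     log-scale OLS residuals, record order
    sigma2_ : float          residual variance s² = RSS / (n - 3)
    n_ : int                 sample size
    exog_ : ndarray          the design matrix [1, ln dbh, ln ht]
    """

    _COEF_NAMES = ("const", "dbh", "ht")

    def __init__(self, back_transform=True, correction="none"):
        self.back_transform = back_transform
        self.correction = correction

    def fit(self, X, y):
        """Fit from raw-scale X = [dbh, ht] columns and raw-scale biomass y."""
        if self.correction not in ("none", "baskerville"):
            raise ValueError(f"unknown correction {self.correction!r}")
        X = check_array(X)
        y = np.asarray(y, dtype=float)
        if X.shape[1] != 2:
            raise ValueError(f"expected 2 columns (dbh, ht), got {X.shape[1]}")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if X.shape[0] < 4:
            raise ValueError(f"need n >= 4 observations, got {X.shape[0]}")
        if np.any(X <= 0) or np.any(y <= 0):
            raise ValueError("dbh, ht and w must be strictly positive for the log fit")
        exog = sm.add_constant(np.log(X), has_constant="add")
        rank = np.linalg.matrix_rank(exog)
        if rank < 3:
            for j, name in enumerate(self._COEF_NAMES[1:], start=1):
                if np.ptp(exog[:, j]) == 0:
                    raise np.linalg.LinAlgError(
                        f"rank-deficient design: ln({name}) is constant")
            raise np.linalg.LinAlgError(
                "rank-deficient design: ln(dbh) and ln(ht) are collinear")
        res = sm.OLS(np.log(y), exog).fit()
        self.results_ = res
        self.a_, self.b_, self.c_ = (float(v) for v in res.params)
        self.residuals_ = np.asarray(res.resid)
        self.n_ = int(res.nobs)
        self.sigma2_ = float(res.ssr / (self.n_ - 3))
        self.exog_ = exog
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        check_is_fitted(self, "a_")
        X = check_array(X)
        if np.any(X <= 0):
            raise ValueError("dbh and ht must be strictly positive")
        ln_pred = self.a_ + self.b_ * np.log(X[:, 0]) + self.c_ * np.log(X[:, 1])
        if not self.back_transform:
            return ln_pred
        w = np.exp(ln_pred)
        if self.correction == "baskerville":
            w = w * np.exp(self.sigma2_ / 2.0)
        return w

    def loo_predict_log(self) -> np.ndarray:
        """Leave-one-out log-scale predictions via the hat matrix (PRESS).

        For OLS the LOO residual is e_i / (1 - h_ii) with h_ii the leverage,
        so no model needs refitting.
        """
        check_is_fitted(self, "a_")
        h = self.results_.get_influence().hat_matrix_diag
        e_loo = self.residuals_ / (1.0 - h)
        return np.asarray(self.results_.model.endog) - e_loo

    def prediction_set(self, loo: bool = False) -> PredictionSet:
        """In-sample (or LOO) predictions as an original-scale PredictionSet."""
        check_is_fitted(self, "a_")
        ln_actual = np.asarray(self.results_.model.endog)
        ln_pred = self.loo_predict_log() if loo else np.asarray(self.results_.fittedvalues)
        pred = np.exp(ln_pred)
        if self.correction == "baskerville":
            pred = pred * np.exp(self.sigma2_ / 2.0)
        return PredictionSet(actual=np.exp(ln_actual), predicted=pred,
                             scale="original", config=self)


def fit_schumacher_hall(ds: TreeDataset) -> SchumacherHallRegressor:
    """Fit the Schumacher-Hall model to a raw-scale tree dataset."""
    if ds.transform_state != "raw":
        raise ValueError("fit_schumacher_hall expects a raw-scale dataset")
    X, y = extract_features(ds, ("dbh", "ht"))
    return SchumacherHallRegressor().fit(X, y)


def predict_biomass(model: SchumacherHallRegressor, dbh, ht,
                    back_transform: bool = True, correction: str = "none"):
    """Evaluate a fitted model at given dbh (cm) and ht (m).

    Scalar in, scalar out; arrays broadcast elementwise.
    """
    check_is_fitted(model, "a_")
    dbh = np.asarray(dbh, dtype=float)
    ht = np.asarray(ht, dtype=float)
    if np.any(dbh <= 0) or np.any(ht <= 0):
        raise ValueError("dbh and ht must be strictly positive")
    ln_pred = model.a_ + model.b_ * np.log(dbh) + model.c_ * np.log(ht)
    if not back_transform:
        return ln_pred if ln_pred.ndim else float(ln_pred)
    w = np.exp(ln_pred)
    if correction == "baskerville":
        w = w * np.exp(model.sigma2_ / 2.0)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    return w if w.ndim else float(w)


def durbin_watson_stat(residuals) -> float:
    """DW = Σ(e_t - e_{t-1})² / Σe_t² over the given residual order."""
    return float(durbin_watson(np.asarray(residuals, dtype=float)))


def run_diagnostics(model: SchumacherHallRegressor,
                    design: np.ndarray | None = None) -> DiagnosticsReport:
    """Residual diagnostics of a fitted model.

    ``design`` defaults to the design matrix stored at fit time; pass it
    explicitly only to diagnose against an alternative exogenous set.  The
    White statistic is n·R² of the auxiliary regression of squared residuals
    on the predictors, their squares and cross-product (chi-square reference
    with the auxiliary slope count as degrees of freedom).  Durbin-Watson
    uses the record order of the fit.
    """
    check_is_fitted(model, "a_")
    exog = model.exog_ if design is None else np.asarray(design, dtype=float)
    if exog.shape[0] != model.n_:
        raise ValueError("design does not match the fitted sample size")
    resid = model.residuals_
    sw_W, sw_p = stats.shapiro(resid)
    lm, lm_p, _, _ = het_white(resid, exog)
    dw = float(durbin_watson(resid))
    return DiagnosticsReport(
        shapiro_wilk_W=float(sw_W), shapiro_wilk_p=float(sw_p),
        white_LM=float(lm), white_p=float(lm_p), durbin_watson=dw)
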