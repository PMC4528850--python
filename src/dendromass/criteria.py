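"""Model-selection criteria applied uniformly to kNN and allometric fits.

All criteria are functions of the residuals e_i = w_i - w_hat_i of a
:class:`~dendromass.neighbors.PredictionSet`:

    R^2     = 1 - RSS / TSS
    R^2_adj = 1 - (n-1)/(n-k) * (1 - R^2)            k = model parameter count
    Syx     = sqrt(RSS / (n-k))                       response units
    AIC     = n * ln(RSS/n) + 2 k'                    k' = k + 1
    AICc    = n * ln(RSS/n) + 2 k' n / (n - k' - 1)
    BIC     = n * ln(RSS/n) + ln(n) * k'

The information criteria use k' = k + 1, the extra degree of freedom being
the residual variance.  For kNN configurations, which have no parametric
coefficient count, k is taken as the number of predictor variables in the
configuration (overridable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .neighbors import PredictionSet

CRITERIA_FIELDS = ("r2", "r2_adj", "syx", "aic", "aicc", "bic")
#: sort direction per criterion: True = smaller is better
ASCENDING = {"r2": False, "r2_adj": False, "syx": True, "aic": True,
             "aicc": True, "bic": True}


@dataclass(frozen=True)
class CriteriaSet:
    """Goodness-of-fit summary of one model/configuration."""

    r2: float
    r2_adj: float
    syx: float
    aic: float
    aicc: float
    bic: float
    k_params: int          # k entering R2adj and Syx
    k_eff: int             # k + 1, entering the information criteria
    n: int
    rss: float
    residuals: np.ndarray
    aicc_recommended: bool  # small-sample rule n / k_eff < 40

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in CRITERIA_FIELDS}


def compute_criteria(preds: PredictionSet, n_params: int) -> CriteriaSet:
    """All selection criteria for one prediction set.

    ``n_params`` is the model's parameter count k (3 for Schumacher-Hall;
    the number of predictor variables for a kNN configuration).  Requires
    n >= n_params + 2 so every denominator is positive.
    """
    w = np.asarray(preds.actual, dtype=float)
    what = np.asarray(preds.predicted, dtype=float)
    n = w.size
    k = int(n_params)
    if k < 1:
        raise ValueError(f"n_params must be >= 1, got {n_params}")
    if n < k + 2:
        raise ValueError(f"need n >= n_params + 2 = {k + 2}, got n = {n}")
    if not (np.all(np.isfinite(w)) and np.all(np.isfinite(what))):
        raise ValueError("non-finite actual or predicted values")
    e = w - what
    rss = float(np.sum(e**2))
    tss = float(np.sum((w - w.mean()) ** 2))
    if tss == 0.0:
        raise ZeroDivisionError("zero response variance: R^2 undefined")
    r2 = 1.0 - rss / tss
    r2_adj = 1.0 - (n - 1) / (n - k) * (1.0 - r2)
    syx = float(np.sqrt(rss / (n - k)))
    k_eff = k + 1
    if rss == 0.0:
        warnings.warn("zero residual sum of squares: information criteria are -inf")
        aic = aicc = bic = -np.inf
    else:
        base = n * np.log(rss / n)
        aic = base + 2.0 * k_eff
        denom = n - k_eff - 1
        aicc = base + 2.0 * k_eff * n / denom if denom > 0 else np.inf
        bic = base + np.log(n) * k_eff
    return CriteriaSet(
        r2=float(r2), r2_adj=float(r2_adj), syx=syx,
        aic=float(aic), aicc=float(aicc), bic=float(bic),
        k_params=k, k_eff=k_eff, n=n, rss=rss, residuals=e,
        aicc_recommended=bool(n / k_eff < 40))


def syx_gain(reference, candidate) -> float:
    """Percent reduction in Syx of ``candidate`` relative to ``reference``.

    Positive when the candidate has the smaller standard error of estimate.
    Accepts CriteriaSet objects or bare Syx values.
    """
    ref = getattr(reference, "syx", reference)
    cand = getattr(candidate, "syx", candidate)
    if ref == 0:
        raise ZeroDivisionError("reference Syx is zero: gain undefined")
    return 100.0 * (ref - cand) / ref


def rank_models(sets, criterion: str = "syx") -> list[int]:
    """Indices of the input criteria sets, best model first.

    Ascending for Syx/AIC/AICc/BIC, descending for R²/R²adj; ties keep input
    order.  Criteria computed on different sample sizes are not directly
    comparable, so mixed n only warns.
    """
    sets = list(sets)
    if len(sets) < 2:
        raise ValueError("rank_models needs at least 2 criteria sets")
    if criterion not in ASCENDING:
        raise ValueError(f"unknown criterion {criterion!r}; valid: {tuple(ASCENDING)}")
    if len({cs.n for cs in sets}) > 1:
        warnings.warn("ranking criteria computed on different sample sizes")
    vals = np.array([getattr(cs, criterion) for cs in sets])
    if not ASCENDING[criterion]:
        vals = -vals
    return list(np.argsort(vals, kind="stable"))


def criteria_table(entries) -> pd.DataFrame:
    """Tabulate ``(label, CriteriaSet)`` pairs, one row per configuration."""
    rows = []
    for label, cs in entries:
        row = {"config": label, "n": cs.n, "k_params": cs.k_params, "k_eff": cs.k_eff}
        row.update(cs.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
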