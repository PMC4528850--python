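"""Instance-based (k-nearest-neighbor) biomass estimation.

A query tree's biomass is predicted as the inverse-distance-weighted mean of
the biomass of its k nearest trees in predictor space,

    w_hat = sum_i u_i * w_i / sum_i u_i,   u_i = 1/d_i  or  1/d_i**2.

The estimator is evaluated by leave-one-out cross-validation: every tree is
predicted from all the other trees in the sample, never from itself.

:class:`KNNBiomassRegressor` is a scikit-learn style estimator (fit/predict,
``get_params``/``set_params``) and composes with sklearn model selection;
:func:`loocv_predict` is the benchmark entry point that operates directly on
a :class:`~dendromass.data.TreeDataset` and a :class:`KNNConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .data import PREDICTORS, TreeDataset, canonical_subset, extract_features, log_transform
from .distances import METRICS, pairwise_distances

WEIGHTINGS = ("inv_d", "inv_d2")
#: neighbor counts of the canonical benchmark grid
CANONICAL_K = (1, 3, 5, 7, 9, 11)


@dataclass(frozen=True)
class KNNConfig:
    """One complete method configuration for the benchmark sweep."""

    metric: str = "chebyshev"
    k_neighbors: int = 5
    weighting: str = "inv_d"
    variables: tuple[str, ...] = PREDICTORS
    use_log: bool = False
    standardize: bool = False
    literal_manhattan: bool = False

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; valid: {METRICS}")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"unknown weighting {self.weighting!r}; valid: {WEIGHTINGS}")
        if self.k_neighbors < 1:
            raise ValueError(f"k_neighbors must be >= 1, got {self.k_neighbors}")
        if self.k_neighbors not in CANONICAL_K:
            warnings.warn(
                f"k_neighbors={self.k_neighbors} is outside the canonical grid "
                f"{CANONICAL_K}", stacklevel=2)
        object.__setattr__(self, "variables", canonical_subset(self.variables))

    def describe(self) -> str:
        tag = "log" if self.use_log else "raw"
        return f"{self.metric}/{self.weighting}/k={self.k_neighbors}/{'+'.join(self.variables)}/{tag}"


@dataclass(frozen=True)
class NeighborSet:
    """The k nearest records to one query, distances ascending."""

    indices: np.ndarray
    record_ids: np.ndarray
    distances: np.ndarray
    biomass: np.ndarray

    def __post_init__(self):
        if len(self.distances) and np.any(np.diff(self.distances) < 0):
            raise ValueError("neighbor distances must be sorted ascending")


@dataclass(frozen=True)
class PredictionSet:
    """Paired (actual, predicted) biomass for every record of a dataset."""

    actual: np.ndarray
    predicted: np.ndarray
    scale: str  # "original" | "log"
    config: object = None

    def __post_init__(self):
        if len(self.actual) != len(self.predicted):
            raise ValueError("actual and predicted must have equal length")
        if not np.all(np.isfinite(self.predicted)):
            raise ValueError("predictions must be finite")

    @property
    def n(self) -> int:
        return len(self.actual)

    def back_transformed(self) -> "PredictionSet":
        """Exponentiate a log-scale prediction set onto the original scale."""
        if self.scale == "original":
            return self
        return PredictionSet(
            actual=np.exp(self.actual), predicted=np.exp(self.predicted),
            scale="original", config=self.config)


def weighted_estimate(neighbors: NeighborSet, weighting: str) -> float:
    """Inverse-distance weighted mean of the neighbors' biomass.

    With any zero-distance neighbor the weights diverge; the prediction then
    degenerates (as the limit d -> 0 of the weighting) to the unweighted mean
    of the zero-distance neighbors alone.
    """
    if weighting not in WEIGHTINGS:
        raise ValueError(f"unknown weighting {weighting!r}")
    d = np.asarray(neighbors.distances, dtype=float)
    y = np.asarray(neighbors.biomass, dtype=float)
    if d.size == 0:
        raise ValueError("empty neighbor set")
    zero = d == 0.0
    if np.any(zero):
        return float(np.mean(y[zero]))
    u = 1.0 / d if weighting == "inv_d" else 1.0 / d**2
    return float(np.sum(u * y) / np.sum(u))


def _neighbor_indices(D_row: np.ndarray, k: int) -> np.ndarray:
    # stable argsort => ties at the k-th boundary break by ascending position
    return np.argsort(D_row, kind="stable")[:k]


def find_neighbors(query_index: int, ds: TreeDataset, config: KNNConfig) -> NeighborSet:
    """The query record's k nearest neighbors among the other records.

    Ties in distance are broken by ascending record position, so the result
    is deterministic and reproducible under any ordering of equal distances.
    """
    if config.k_neighbors >= ds.n:
        raise ValueError(f"k_neighbors={config.k_neighbors} must be < n={ds.n} under LOOCV")
    ds_t = log_transform(ds) if config.use_log else ds
    X, y = extract_features(ds_t, config.variables)
    if config.standardize:
        X = _zscore(X)
    q = X[query_index][None, :]
    D = pairwise_distances(X, q, config.metric, config.literal_manhattan)[0]
    D[query_index] = np.inf
    idx = _neighbor_indices(D, config.k_neighbors)
    return NeighborSet(
        indices=idx, record_ids=ds.record_ids[idx], distances=D[idx], biomass=y[idx])


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _predict_rows(D: np.ndarray, y: np.ndarray, k: int, weighting: str) -> np.ndarray:
    """Vectorized weighted estimates for every row of a distance matrix."""
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    d = np.take_along_axis(D, order, axis=1)
    ynb = y[order]
    zero = d == 0.0
    with np.errstate(divide="ignore"):
        u = 1.0 / d if weighting == "inv_d" else 1.0 / d**2
    preds = np.empty(D.shape[0])
    any_zero = zero.any(axis=1)
    if np.any(any_zero):
        rows = np.flatnonzero(any_zero)
        for i in rows:
            preds[i] = ynb[i][zero[i]].mean()
    rest = ~any_zero
    if np.any(rest):
        preds[rest] = np.sum(u[rest] * ynb[rest], axis=1) / np.sum(u[rest], axis=1)
    return preds


class KNNBiomassRegressor(RegressorMixin, BaseEstimator):
    """Distance-weighted k-nearest-neighbor regressor for tree biomass.

    Parameters
    ----------
    n_neighbors : int, default 5
        Neighborhood size; the benchmark grid uses {1, 3, 5, 7, 9, 11}.
    metric : {"euclidean", "quadratic_euclidean", "manhattan", "chebyshev"}
        Distance on the raw (unstandardized) feature coordinates.
    weighting : {"inv_d", "inv_d2"}
        Neighbor weights 1/d or 1/d².  Zero-distance neighbors receive the
        limit behaviour: their unweighted mean is returned.
    standardize : bool, default False
        Z-score features on fit.  Off by default: the benchmark protocol
        uses native units.
    literal_manhattan : bool, default False
        Audit switch; see :mod:`dendromass.distances`.

    Examples
    --------
    >>> est = KNNBiomassRegressor(n_neighbors=3, metric="chebyshev")
    >>> est.fit(X_train, y_train).predict(X_new)          # doctest: +SKIP
    """

    def __init__(self, n_neighbors=5, metric="chebyshev", weighting="inv_d",
                 standardize=False, literal_manhattan=False):
        self.n_neighbors = n_neighbors
        self.metric = metric
        self.weighting = weighting
        self.standardize = standardize
        self.literal_manhattan = literal_manhattan

    def _validate_params_(self):
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; valid: {METRICS}")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"unknown weighting {self.weighting!r}; valid: {WEIGHTINGS}")
        if not (isinstance(self.n_neighbors, (int, np.integer)) and self.n_neighbors >= 1):
            raise ValueError(f"n_neighbors must be a positive int, got {self.n_neighbors!r}")

    def fit(self, X, y):
        self._validate_params_()
        X, y = check_X_y(X, y, ensure_min_samples=max(2, self.n_neighbors))
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            self.scale_ = X.std(axis=0)
            self.scale_[self.scale_ == 0] = 1.0
            X = (X - self.mean_) / self.scale_
        self.X_ = X
        self.y_ = y
        self.n_features_in_ = X.shape[1]
        return self

    def _transform(self, X):
        if self.standardize:
            return (X - self.mean_) / self.scale_
        return X

    def kneighbors(self, X):
        """Distances and training indices of each query's k nearest neighbors."""
        check_is_fitted(self, "X_")
        X = self._transform(check_array(X))
        D = pairwise_distances(self.X_, X, self.metric, self.literal_manhattan)
        order = np.argsort(D, axis=1, kind="stable")[:, : self.n_neighbors]
        return np.take_along_axis(D, order, axis=1), order

    def predict(self, X):
        check_is_fitted(self, "X_")
        X = self._transform(check_array(X))
        D = pairwise_distances(self.X_, X, self.metric, self.literal_manhattan)
        return _predict_rows(D, self.y_, self.n_neighbors, self.weighting)

    def loo_predict(self):
        """Leave-one-out predictions for the training records themselves."""
        check_is_fitted(self, "X_")
        if self.n_neighbors >= len(self.y_):
            raise ValueError(
                f"n_neighbors={self.n_neighbors} must be < n={len(self.y_)} under LOOCV")
        D = pairwise_distances(self.X_, None, self.metric, self.literal_manhattan)
        np.fill_diagonal(D, np.inf)
        return _predict_rows(D, self.y_, self.n_neighbors, self.weighting)


def loocv_predict(ds: TreeDataset, config: KNNConfig) -> PredictionSet:
    """Leave-one-out cross-validated predictions for every record.

    Each record is predicted from the remaining n-1 records using the
    configured metric, weighting, neighbor count and variable subset.  With
    ``use_log`` the features *and* response enter on the natural-log scale
    and the returned prediction set is flagged ``scale="log"``.
    """
    if config.k_neighbors >= ds.n:
        raise ValueError(f"k_neighbors={config.k_neighbors} must be < n={ds.n} under LOOCV")
    ds_t = log_transform(ds) if config.use_log else ds
    X, y = extract_features(ds_t, config.variables)
    est = KNNBiomassRegressor(
        n_neighbors=config.k_neighbors, metric=config.metric,
        weighting=config.weighting, standardize=config.standardize,
        literal_manhattan=config.literal_manhattan,
    ).fit(X, y)
    preds = est.loo_predict()
    return PredictionSet(
        actual=y, predicted=preds,
        scale="log" if config.use_log else "original", config=config)
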