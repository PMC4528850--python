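"""Distance metrics used to define tree neighborhoods.

Four metrics on the selected predictor coordinates, for difference vector
``Δ = p - q``:

* ``euclidean``            sqrt(Σ Δ²)
* ``quadratic_euclidean``  Σ Δ²          (the squared Euclidean distance)
* ``manhattan``            Σ |Δ|
* ``chebyshev``            max |Δ|

Variables enter in their native units; no standardization is applied unless
explicitly requested by the caller, so large-range coordinates (dbh in cm)
dominate small-range ones (densities in g/cm3).

``literal_manhattan`` reproduces, for audit, a published variant in which the
"Manhattan" formula sums *squared* absolute differences and therefore
coincides with the quadratic Euclidean distance; the default is the standard
city-block sum that the metric's name denotes.
"""

from __future__ import annotations

import numpy as np

METRICS = ("euclidean", "quadratic_euclidean", "manhattan", "chebyshev")


def _diff_reduce(absdiff: np.ndarray, metric: str, literal_manhattan: bool, axis=-1):
    if metric == "euclidean":
        return np.sqrt(np.sum(absdiff**2, axis=axis))
    if metric == "quadratic_euclidean":
        return np.sum(absdiff**2, axis=axis)
    if metric == "manhattan":
        if literal_manhattan:
            return np.sum(absdiff**2, axis=axis)
        return np.sum(absdiff, axis=axis)
    if metric == "chebyshev":
        return np.max(absdiff, axis=axis)
    raise ValueError(f"unknown metric {metric!r}; valid: {METRICS}")


def compute_distance(p, q, metric: str, literal_manhattan: bool = False) -> float:
    """Distance between two feature vectors under the named metric.

    Vectors must be finite and of equal length >= 1.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.ndim != 1 or q.ndim != 1 or p.shape != q.shape or p.size < 1:
        raise ValueError(f"p and q must be 1-D of equal length >= 1, got {p.shape} and {q.shape}")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("non-finite input to compute_distance")
    return float(_diff_reduce(np.abs(p - q), metric, literal_manhattan))


def pairwise_distances(
    X: np.ndarray,
    Q: np.ndarray | None = None,
    metric: str = "euclidean",
    literal_manhattan: bool = False,
) -> np.ndarray:
    """Dense distance matrix ``D[i, j] = d(Q[i], X[j])`` (``Q = X`` if omitted).

    Exhaustive O(m·n·p) broadcasting; the datasets this package targets are a
    few hundred trees, for which this is both fastest and simplest.
    """
    X = np.asarray(X, dtype=float)
    Q = X if Q is None else np.asarray(Q, dtype=float)
    if X.ndim != 2 or Q.ndim != 2 or X.shape[1] != Q.shape[1]:
        raise ValueError("X and Q must be 2-D with matching feature dimension")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Q))):
        raise ValueError("non-finite input to pairwise_distances")
    absdiff = np.abs(Q[:, None, :] - X[None, :, :])
    return _diff_reduce(absdiff, metric, literal_manhattan)
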