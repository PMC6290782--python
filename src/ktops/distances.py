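"""Distance measures used by the K-means sweep and the validity indices.

Four distances drive K-means assignment (sqEuclidean, Cityblock, Cosine,
Correlation) and seven metrics drive the pairwise distances inside the
validity indices (the four above plus Euclidean, Hamming and Jaccard).
Hamming and Jaccard are set-type measures: two coordinates "differ" iff
their values are not exactly equal, and Jaccard normalizes over the
coordinates where at least one vector is nonzero.  On continuous features
almost every coordinate differs, so these two metrics yield near-constant
pairwise distances and therefore near-constant validity indices -- they
stay in the 4 x 7 grid but contribute neutrally to the CD selection, which
is the faithful behaviour of set-type measures applied to real-valued
vectors.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

KMEANS_DISTANCES = ("sqeuclidean", "cityblock", "cosine", "correlation")
VALIDATION_METRICS = ("sqeuclidean", "euclidean", "cityblock", "cosine",
                      "correlation", "hamming", "jaccard")

_SCIPY_METRICS = {"sqeuclidean", "euclidean", "cityblock", "cosine",
                  "correlation"}


def _exact_hamming(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a[:, None, :] != b[None, :, :]).mean(axis=2)


def _exact_jaccard(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aa = a[:, None, :]
    bb = b[None, :, :]
    nonzero = (aa != 0) | (bb != 0)
    differ = (aa != bb) & nonzero
    denom = nonzero.sum(axis=2)
    with np.errstate(invalid="ignore"):
        d = differ.sum(axis=2) / denom
    return np.where(denom == 0, 0.0, d)


def pairwise(a: np.ndarray, b: np.ndarray | None = None,
             metric: str = "euclidean") -> np.ndarray:
    """Pairwise distance matrix between the rows of ``a`` and ``b``."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = a if b is None else np.atleast_2d(np.asarray(b, dtype=float))
    if metric in _SCIPY_METRICS:
        d = cdist(a, b, metric=metric)
        if metric in ("cosine", "correlation"):
            # zero-variance rows produce NaN; use the maximal distance
            d = np.nan_to_num(d, nan=1.0)
        return d
    if metric == "hamming":
        return _exact_hamming(a, b)
    if metric == "jaccard":
        return _exact_jaccard(a, b)
    raise ValueError(f"unknown metric: {metric}")


def vector_distance(x: np.ndarray, y: np.ndarray, metric: str) -> float:
    return float(pairwise(x[None, :], y[None, :], metric)[0, 0])


def centroid(points: np.ndarray, metric: str) -> np.ndarray:
    """Representative center of a point set under a given metric.

    Mean for (sq)Euclidean-type metrics, component median for Cityblock
    (and the mean for the remaining metrics).
    """
    if metric == "cityblock":
        return np.median(points, axis=0)
    return points.mean(axis=0)
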