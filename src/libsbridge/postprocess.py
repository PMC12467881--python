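"""DBSCAN-based screening of abnormal test spectra (the post-processing stage).

Spectra whose feature vectors fall in no dense region of feature space are
treated as measurement outliers and removed from the test set before
evaluation. DBSCAN labels a point a core point when its epsilon-neighborhood
holds at least ``min_points`` points (the point itself included); core points
and the border points they reach form clusters, everything else is noise.
Only noise is removed — border points are retained.

Epsilon is chosen from the K-Distance Graph: the distance of every point to
its k-th nearest neighbor, sorted ascending, shows an elbow where local
density collapses; the elbow is automated as the point of maximum discrete
curvature (largest second difference) of the smoothed curve, with a manual
override available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .features import FeatureTable

__all__ = ["DbscanConfig", "KDistanceCurve", "kdistance", "dbscan_filter"]


@dataclass
class DbscanConfig:
    """DBSCAN parameters (Euclidean metric)."""

    eps: float = 2.5
    min_points: int = 15
    standardize: bool = False  # z-score features first (off: values are ~[0,1])

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")


@dataclass
class KDistanceCurve:
    """Ascending k-th-nearest-neighbor distances with an elbow estimate."""

    k: int
    distances: np.ndarray  # sorted ascending
    suggested_eps: float
    elbow_index: int


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, FeatureTable):
        return data.matrix
    return np.atleast_2d(np.asarray(data, dtype=float))


def kdistance(data, k: int, smooth_frac: float = 0.02) -> KDistanceCurve:
    """K-Distance Graph of a feature matrix (or FeatureTable).

    Computes the Euclidean distance of each sample to its k-th nearest
    neighbor (self excluded) and sorts ascending. ``suggested_eps`` is the
    distance at the maximum second difference of the moving-average-smoothed
    curve, searched over the curve's interior.
    """
    X = _as_matrix(data)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of rows ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, _ = nn.kneighbors(X)
    curve = np.sort(dist[:, k])
    # smooth with a short moving average, then locate the knee as the point
    # of maximum distance below the chord joining the curve's endpoints
    # (scale-invariant; a raw second difference would lock onto the extreme
    # tail of the steep final ramp instead of the visual elbow)
    w = max(int(round(smooth_frac * n)), 3)
    kernel = np.ones(w) / w
    smoothed = np.convolve(np.pad(curve, w // 2, mode="edge"), kernel, "valid")[
        : curve.size
    ]
    y0, y1 = smoothed[0], smoothed[-1]
    if y1 <= y0 + 1e-300:
        elbow = n - 1
    else:
        x = np.linspace(0.0, 1.0, n)
        y = (smoothed - y0) / (y1 - y0)
        elbow = int(np.argmax(x - y))
    return KDistanceCurve(k, curve, float(smoothed[elbow]), elbow)


def dbscan_filter(
    data, cfg: DbscanConfig
) -> tuple[FeatureTable | np.ndarray, np.ndarray]:
    """Remove DBSCAN noise points from a feature table.

    Returns the retained table (cluster members, core and border) and the
    indices of the removed outliers. Raises when every point is noise — a
    sign that eps is far too small for the data scale.
    """
    X = _as_matrix(data)
    if X.shape[0] < cfg.min_points:
        raise ValueError(
            f"need at least min_points={cfg.min_points} rows, got {X.shape[0]}"
        )
    Z = X
    if cfg.standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - X.mean(axis=0)) / sd
    labels = DBSCAN(eps=cfg.eps, min_samples=cfg.min_points, metric="euclidean").fit(
        Z
    ).labels_
    outliers = np.flatnonzero(labels == -1)
    if outliers.size == X.shape[0]:
        raise ValueError(
            "DBSCAN labeled every point noise; increase eps (try the "
            "K-Distance Graph elbow)"
        )
    retained_idx = np.flatnonzero(labels != -1)
    if isinstance(data, FeatureTable):
        return data.subset_rows(retained_idx), outliers
    return X[retained_idx], outliers
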