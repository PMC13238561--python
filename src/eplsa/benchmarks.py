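"""Baseline state-identification methods: LEiDA clustering and amplitude ELA.

LEiDA (leading-eigenvector dynamics analysis) clusters the per-frame
sign-fixed leading eigenvectors with k-means; each cluster centroid is a
recurrent phase-locking state.  It can run on ROI-level or network-level
input — the caller controls the level through the scan it supplies.

Amplitude-based energy-landscape analysis (ELA) binarizes each network's
BOLD amplitude at its mean (z-score then sign), producing a pattern series
that feeds the same maximum-entropy / landscape / dynamics machinery as
the phase-based front end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .io import ScanRecord
from .phase import BinaryPatternSeries, DegenerateSignalError, LeadingEigSeries


@dataclass
class LeidaModel:
    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    inertia: float
    seed: int


@dataclass
class ClusterQuality:
    dunn: float
    distortion: float


def _as_matrix(eigs) -> np.ndarray:
    if isinstance(eigs, LeadingEigSeries):
        return eigs.vectors
    return np.asarray(eigs, dtype=float)


def leida_fit(eigs, k: int, seed: int, n_init: int = 20) -> LeidaModel:
    """k-means over leading eigenvectors (Euclidean distance, best of n_init).

    Deterministic given ``(seed, n_init)``.  Centroids inherit the sign
    convention of the (sign-fixed) input vectors.
    """
    x = _as_matrix(eigs)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(x):
        raise ValueError(f"k={k} exceeds the {len(x)} available frames")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    assignments = km.fit_predict(x)
    return LeidaModel(
        k=k,
        centroids=km.cluster_centers_,
        assignments=assignments,
        inertia=float(km.inertia_),
        seed=seed,
    )


def cluster_occupancy(model: LeidaModel) -> np.ndarray:
    """Fraction of frames assigned to each cluster (sums to 1)."""
    return np.bincount(model.assignments, minlength=model.k) / len(model.assignments)


def cluster_quality(eigs, model: LeidaModel) -> ClusterQuality:
    """Dunn index and distortion of a fitted clustering.

    Dunn = (minimum inter-cluster point distance) / (maximum intra-cluster
    diameter); +inf if every cluster has zero diameter.  Distortion is the
    k-means inertia: the sum of squared distances to assigned centroids.
    """
    x = _as_matrix(eigs)
    labels = model.assignments
    if model.k < 2:
        raise ValueError("Dunn index undefined for fewer than 2 clusters")
    counts = np.bincount(labels, minlength=model.k)
    if np.any(counts == 0):
        raise ValueError(f"empty cluster(s): {np.flatnonzero(counts == 0).tolist()}")
    d = squareform(pdist(x))
    same = labels[:, None] == labels[None, :]
    inter = d[~same].min()
    np.fill_diagonal(same, False)
    intra = d[same].max() if same.any() else 0.0
    dunn = float("inf") if intra == 0 else float(inter / intra)
    distortion = float(((x - model.centroids[labels]) ** 2).sum())
    return ClusterQuality(dunn=dunn, distortion=distortion)


def ela_binarize(scan: ScanRecord, threshold: float = 0.0) -> BinaryPatternSeries:
    """Amplitude binarization: z-score each column, then sign at ``threshold``.

    A value strictly above the threshold maps to +1 (active), otherwise -1.
    The z-scoring makes the result invariant to positive rescaling of any
    column; the default threshold 0 binarizes at the column mean.
    """
    sd = scan.data.std(axis=0)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        raise DegenerateSignalError(
            f"column {scan.region_labels[j]!r} is constant; cannot z-score"
        )
    z = (scan.data - scan.data.mean(axis=0)) / sd
    return BinaryPatternSeries.from_patterns(np.where(z > threshold, 1, -1))
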