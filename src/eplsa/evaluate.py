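"""Evaluation statistics: MNR discriminability and symmetrized KL divergence.

The mean-nearest-rank (MNR) discriminability index measures test-retest
reliability: for each within-subject measurement pair it ranks the pair's
distance against that measurement's between-subject distances, and averages
the tie-corrected ranks.  MNR is 1 when every within-subject distance beats
every between-subject distance, and about 0.5 when features carry no
subject information.

The symmetrized Kullback-Leibler divergence compares state-occupancy
distributions between two conditions:

    KL_sym(P, Q) = 0.5 * [sum_i P_i ln(P_i / Q_i) + sum_i Q_i ln(Q_i / P_i)]

with additive smoothing applied only when either distribution has zeros
(a state unvisited in one condition).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


@dataclass
class MeasurementSet:
    """Feature rows (one per measurement) with subject/session identifiers."""

    features: np.ndarray
    subject_of: list[str]
    session_of: list[str]
    condition_of: list[str] | None = None
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        m = self.features.shape[0]
        if m < 2:
            raise ValueError("need at least 2 measurements")
        if len(self.subject_of) != m or len(self.session_of) != m:
            raise ValueError("subject/session lists must match feature rows")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")

    @property
    def n_measurements(self) -> int:
        return self.features.shape[0]

    def to_frame(self) -> pd.DataFrame:
        names = self.feature_names or [
            f"f{i}" for i in range(self.features.shape[1])
        ]
        df = pd.DataFrame(self.features, columns=names)
        df.insert(0, "session", self.session_of)
        df.insert(0, "subject", self.subject_of)
        if self.condition_of is not None:
            df.insert(2, "condition", self.condition_of)
        return df


def distance_matrix(ms: MeasurementSet) -> np.ndarray:
    """Pairwise Euclidean distances between feature rows (M x M, symmetric).

    Matrix-valued features (e.g. connectivity matrices) should be supplied
    flattened, one matrix per row.
    """
    return squareform(pdist(ms.features, metric="euclidean"))


def mnr(D: np.ndarray, subject_of: list[str]) -> float:
    """Mean nearest-rank discriminability of a distance matrix.

    For every ordered within-subject pair (i, j), i != j, all same-subject
    distances are excluded from row i's comparison pool and

        r_ij = 1 - [#(between < D_ij) + 0.5 * #(between = D_ij)] / (N - S)

    where N is the total number of measurements and S the number of
    measurements of i's subject.  MNR is the mean of all r_ij and, being
    rank-based, is invariant to any strictly increasing transform of the
    distances.
    """
    D = np.asarray(D, dtype=float)
    subjects = np.asarray(subject_of)
    n = len(subjects)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match subjects")
    if len(np.unique(subjects)) < 2:
        raise ValueError("MNR needs at least 2 distinct subjects")
    ranks = []
    for i in range(n):
        same = subjects == subjects[i]
        s = int(same.sum())
        if s < 2:
            continue
        pool = D[i, ~same]
        denom = n - s
        for j in np.flatnonzero(same):
            if j == i:
                continue
            d = D[i, j]
            below = int((pool < d).sum())
            ties = int((pool == d).sum())
            ranks.append(1.0 - (below + 0.5 * ties) / denom)
    if not ranks:
        raise ValueError("MNR needs at least one subject with repeated measurements")
    return float(np.mean(ranks))


def sym_kl(p: np.ndarray, q: np.ndarray, eps: float = 1e-10) -> float:
    """Symmetrized KL divergence between two discrete distributions.

    ``eps`` additive smoothing (followed by renormalization) is applied to
    both distributions only when either contains a zero.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("p and q must be 1-D with equal length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("distributions must be nonnegative")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-8:
            raise ValueError(f"{name} must sum to 1")
    if np.any(p == 0) or np.any(q == 0):
        p = p + eps
        q = q + eps
        p = p / p.sum()
        q = q / q.sum()
    return float(0.5 * (np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p))))


def pairwise_kl(occupancies: dict[str, np.ndarray], eps: float = 1e-10) -> pd.DataFrame:
    """Symmetrized KL for every unordered pair of conditions.

    For C conditions this yields C*(C-1)/2 rows (28 for the canonical
    eight-condition rest-plus-tasks design).
    """
    rows = [
        {"condition_a": a, "condition_b": b, "sym_kl": sym_kl(
            occupancies[a], occupancies[b], eps=eps
        )}
        for a, b in combinations(occupancies, 2)
    ]
    return pd.DataFrame(rows, columns=["condition_a", "condition_b", "sym_kl"])


def majority_map(
    est_labels: np.ndarray, ref_labels: np.ndarray, n_est: int, n_ref: int
) -> np.ndarray:
    """Map each estimated state to the reference state it most overlaps.

    Standard cluster-recovery correspondence: estimated state ``s`` maps to
    the reference label holding the majority of the frames assigned to
    ``s``.  Used to compare an estimated state sequence against a known
    generating process when the estimated state count may exceed the true
    one (e.g. spurious transition-frame basins).
    """
    est_labels = np.asarray(est_labels)
    ref_labels = np.asarray(ref_labels)
    if est_labels.shape != ref_labels.shape:
        raise ValueError("label sequences must have equal length")
    mapping = np.zeros(n_est, dtype=np.int64)
    for s in range(n_est):
        mask = est_labels == s
        if mask.any():
            mapping[s] = np.bincount(ref_labels[mask], minlength=n_ref).argmax()
    return mapping


def occupancy_features(
    metrics_list,
    subject_of: list[str],
    session_of: list[str],
    condition_of: list[str] | None = None,
    n_states: int | None = None,
) -> MeasurementSet:
    """Per-scan state occurrence-frequency feature table.

    One row per scan; columns span the common state universe (the maximum
    state count across scans unless ``n_states`` widens it), zero-filled
    for states a scan never visits.  The table is the input any standard
    classifier consumes for condition decoding.
    """
    freqs = [np.asarray(m.occurrence_frequency, dtype=float) for m in metrics_list]
    width = max(len(f) for f in freqs)
    if n_states is not None:
        width = max(width, n_states)
    features = np.zeros((len(freqs), width))
    for i, f in enumerate(freqs):
        features[i, : len(f)] = f
    return MeasurementSet(
        features=features,
        subject_of=list(subject_of),
        session_of=list(session_of),
        condition_of=list(condition_of) if condition_of is not None else None,
        feature_names=[f"state{i}" for i in range(width)],
    )
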