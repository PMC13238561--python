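"""Instantaneous phases, phase-locking matrices, leading eigenvectors, binarization.

This is the front end of energy-based phase-locking state analysis.  Each
network BOLD series is demeaned and Hilbert-transformed to obtain an
instantaneous phase ``phi_j(t)``; pairwise synchrony at frame ``t`` is the
dynamic phase-locking (dPL) matrix ``cos(phi_i - phi_j)``; the leading
eigenvector of each dPL matrix summarizes the dominant synchronization mode
and is binarized at zero into an activity pattern sigma in {-1,+1}^N.

Pattern codes
-------------
A pattern sigma is encoded as an integer in ``[0, 2^N)`` with the fixed
convention +1 -> bit 1, -1 -> bit 0, and unit 0 (the first network) as the
most significant bit, so decoding a code always reproduces the pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.signal

from .io import NetworkMap, ScanRecord, aggregate_networks


class DegenerateSignalError(ValueError):
    """Raised when a column has zero variance and admits no phase."""


class ValidationError(ValueError):
    """Raised when a numeric precondition (symmetry, index range) fails."""


# ---------------------------------------------------------------------------
# pattern coding


def encode_patterns(patterns: np.ndarray) -> np.ndarray:
    """Encode rows of a (T x N) +/-1 matrix as integer codes.

    Unit 0 is the most significant bit; +1 maps to bit value 1.
    """
    patterns = np.asarray(patterns)
    if not np.all(np.isin(patterns, (-1, 1))):
        raise ValidationError("patterns must contain only -1 and +1")
    n = patterns.shape[-1]
    bits = (patterns + 1) // 2
    weights = 1 << np.arange(n - 1, -1, -1)
    return bits @ weights


def decode_codes(codes: np.ndarray, n_units: int) -> np.ndarray:
    """Decode integer codes into a (T x N) matrix of +/-1 entries."""
    codes = np.atleast_1d(np.asarray(codes, dtype=np.int64))
    if np.any(codes < 0) or np.any(codes >= (1 << n_units)):
        raise ValidationError(f"codes must lie in [0, 2^{n_units})")
    shifts = np.arange(n_units - 1, -1, -1)
    bits = (codes[:, None] >> shifts) & 1
    return bits * 2 - 1


@lru_cache(maxsize=None)
def _all_patterns_cached(n_units: int) -> np.ndarray:
    pats = decode_codes(np.arange(1 << n_units), n_units)
    pats.setflags(write=False)
    return pats


def all_patterns(n_units: int) -> np.ndarray:
    """All 2^N patterns in code order, as a read-only (2^N x N) +/-1 matrix."""
    if n_units < 1 or n_units > 24:
        raise ValidationError("n_units must be in [1, 24] for enumeration")
    return _all_patterns_cached(n_units)


@dataclass
class BinaryPatternSeries:
    """Per-frame activity patterns sigma in {-1,+1}^N with integer codes."""

    patterns: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=int)
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.patterns.ndim != 2:
            raise ValidationError("patterns must be 2-D (frames x units)")
        if len(self.codes) != self.patterns.shape[0]:
            raise ValidationError("codes and patterns must have equal length")
        if not np.array_equal(encode_patterns(self.patterns), self.codes):
            raise ValidationError("codes do not encode the stored patterns")

    @classmethod
    def from_patterns(cls, patterns: np.ndarray) -> "BinaryPatternSeries":
        patterns = np.asarray(patterns, dtype=int)
        return cls(patterns=patterns, codes=encode_patterns(patterns))

    @classmethod
    def from_codes(cls, codes: np.ndarray, n_units: int) -> "BinaryPatternSeries":
        codes = np.asarray(codes, dtype=np.int64)
        return cls(patterns=decode_codes(codes, n_units), codes=codes)

    @property
    def n_frames(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_units(self) -> int:
        return self.patterns.shape[1]


# ---------------------------------------------------------------------------
# phases


@dataclass
class PhaseSeries:
    """Instantaneous phases (radians, in (-pi, pi]) with an edge-trimmed valid range."""

    phases: np.ndarray
    valid_start: int
    valid_stop: int  # exclusive
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if not np.all(np.isfinite(self.phases)):
            raise ValidationError("phases must be finite")
        if not (0 <= self.valid_start < self.valid_stop <= len(self.phases)):
            raise ValidationError("invalid trim range")

    @property
    def n_frames(self) -> int:
        return self.phases.shape[0]

    @property
    def n_units(self) -> int:
        return self.phases.shape[1]

    @property
    def valid_frames(self) -> range:
        return range(self.valid_start, self.valid_stop)


def hilbert_phase(scan: ScanRecord, trim: int = 1) -> PhaseSeries:
    """Instantaneous phase of each (demeaned) column via the analytic signal.

    Parameters
    ----------
    scan:
        Time series, T >= 4 frames.  Columns are demeaned before the
        transform; any temporal filtering is assumed done upstream.
    trim:
        Number of frames flagged invalid at each end to suppress Hilbert
        edge effects.

    Returns
    -------
    PhaseSeries
        ``phases[t, j]`` is the quadrant-aware angle of the analytic signal
        of column ``j`` at frame ``t``, wrapped into ``(-pi, pi]``.
    """
    t = scan.n_frames
    if t < 4:
        raise ValidationError(f"need at least 4 frames for phase estimation, got {t}")
    if trim < 0 or 2 * trim >= t:
        raise ValidationError(f"trim={trim} leaves no valid frames for T={t}")
    x = scan.data - scan.data.mean(axis=0)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        raise DegenerateSignalError(
            f"column {scan.region_labels[j]!r} is constant; phase undefined"
        )
    analytic = scipy.signal.hilbert(x, axis=0)
    phases = np.angle(analytic)
    phases = np.where(phases <= -np.pi, phases + 2 * np.pi, phases)
    return PhaseSeries(
        phases=phases,
        valid_start=trim,
        valid_stop=t - trim,
        labels=list(scan.region_labels),
    )


def dpl_matrix(phases: PhaseSeries, t: int) -> np.ndarray:
    """Dynamic phase-locking matrix at frame ``t``: ``cos(phi_i - phi_j)``.

    Symmetric with unit diagonal; entries in [-1, 1].
    """
    if t not in phases.valid_frames:
        raise ValidationError(
            f"frame {t} outside valid range "
            f"[{phases.valid_start}, {phases.valid_stop})"
        )
    phi = phases.phases[t]
    return np.cos(phi[:, None] - phi[None, :])


def dpl_tensor(phases: PhaseSeries) -> np.ndarray:
    """Stack of dPL matrices over the valid range, shape (N, N, T_valid)."""
    phi = phases.phases[phases.valid_start : phases.valid_stop]
    return np.cos(phi[:, :, None] - phi[:, None, :]).transpose(1, 2, 0)


# ---------------------------------------------------------------------------
# leading eigenvector


def sign_fix(v: np.ndarray) -> np.ndarray:
    """Orient an eigenvector so that more components are negative than positive.

    Zero components count as negative.  On an exact tie the vector is
    oriented so its largest-magnitude component (first such index) is
    non-positive.  Binarization after this fix is invariant to the raw
    eigenvector's arbitrary global sign.
    """
    v = np.asarray(v, dtype=float)
    n = len(v)
    pos = int(np.sum(v > 0))
    strictly_neg = int(np.sum(v < 0))
    score_keep = (n - pos) - pos  # negatives minus positives, zeros negative
    score_flip = (n - strictly_neg) - strictly_neg
    if score_keep > score_flip:
        return v
    if score_flip > score_keep:
        return -v
    i = int(np.argmax(np.abs(v)))
    return v if v[i] <= 0 else -v


def leading_eig(dpl: np.ndarray, sym_tol: float = 1e-10) -> tuple[np.ndarray, float]:
    """Unit leading eigenvector (sign-fixed) and largest eigenvalue of a dPL matrix.

    The matrix must be symmetric within ``sym_tol``.  A degenerate leading
    eigenvalue is resolved by the deterministic symmetric eigensolver on the
    matrix in canonical unit order, then sign-fixed.
    """
    dpl = np.asarray(dpl, dtype=float)
    if dpl.ndim != 2 or dpl.shape[0] != dpl.shape[1]:
        raise ValidationError("dPL matrix must be square")
    if np.max(np.abs(dpl - dpl.T)) > sym_tol:
        raise ValidationError("dPL matrix is not symmetric within tolerance")
    w, vecs = np.linalg.eigh(dpl)
    v = sign_fix(vecs[:, -1])
    return v, float(w[-1])


@dataclass
class LeadingEigSeries:
    """Per-frame sign-fixed leading eigenvectors and their eigenvalues."""

    vectors: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.vectors.ndim != 2 or len(self.eigenvalues) != len(self.vectors):
            raise ValidationError("vectors/eigenvalues shape mismatch")

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[0]


def leading_eig_series(phases: PhaseSeries) -> LeadingEigSeries:
    """Leading eigenvector of the dPL matrix at every valid frame."""
    frames = phases.valid_frames
    n = phases.n_units
    vectors = np.empty((len(frames), n))
    eigenvalues = np.empty(len(frames))
    for k, t in enumerate(frames):
        vectors[k], eigenvalues[k] = leading_eig(dpl_matrix(phases, t))
    return LeadingEigSeries(vectors=vectors, eigenvalues=eigenvalues)


def binarize(v: np.ndarray) -> np.ndarray:
    """Binarize a sign-fixed vector at zero: > 0 -> +1 (active), <= 0 -> -1."""
    return np.where(np.asarray(v) > 0, 1, -1)


def phase_pipeline(
    scan: ScanRecord,
    netmap: NetworkMap | None = None,
    trim: int = 1,
) -> BinaryPatternSeries:
    """Full front end: aggregate -> phases -> dPL -> leading eigenvector -> binarize.

    Returns one pattern per valid frame (length ``T - 2 * trim``).
    """
    if netmap is not None:
        scan = aggregate_networks(scan, netmap)
    phases = hilbert_phase(scan, trim=trim)
    eigs = leading_eig_series(phases)
    return BinaryPatternSeries.from_patterns(binarize(eigs.vectors))
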