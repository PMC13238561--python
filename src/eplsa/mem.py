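"""Pairwise maximum-entropy (Ising) model over binary activity patterns.

The model assigns each pattern sigma in {-1,+1}^N the energy

    E(sigma | h, J) = - sum_i h_i sigma_i - (1/2) sum_{i != j} J_ij sigma_i sigma_j

and the Boltzmann probability P(sigma) = exp(-E(sigma)) / Z.  Here ``h_i``
is the basal activity of unit i and ``J_ij = J_ji`` (with ``J_ii = 0``) the
pairwise interaction.  Maximum entropy fixes (h, J) by matching the model's
first and second moments, <sigma_i> and <sigma_i sigma_j>, to the empirical
ones; fitting is exact-gradient ascent on the log-likelihood, which for
N <= ~15 units is tractable by full enumeration of the 2^N patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .phase import BinaryPatternSeries, all_patterns


class CapacityError(ValueError):
    """Raised when N is too large for exact enumeration."""


class FitError(RuntimeError):
    """Raised when gradient ascent diverges."""


_MAX_ENUM_UNITS = 20


@dataclass
class MEMParams:
    """Basal activities ``h`` (length N) and symmetric zero-diagonal couplings ``J``."""

    h: np.ndarray
    J: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        n = len(self.h)
        if self.J.shape != (n, n):
            raise ValueError("J must be N x N with N = len(h)")
        if np.max(np.abs(self.J - self.J.T)) > 1e-10:
            raise ValueError("J must be symmetric")
        if np.max(np.abs(np.diag(self.J))) > 1e-12:
            raise ValueError("J must have zero diagonal")
        # store exactly symmetric / zero-diagonal
        self.J = (self.J + self.J.T) / 2.0
        np.fill_diagonal(self.J, 0.0)

    @property
    def n_units(self) -> int:
        return len(self.h)

    def to_dict(self) -> dict:
        return {"h": self.h.tolist(), "J": self.J.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "MEMParams":
        return cls(h=np.array(d["h"]), J=np.array(d["J"]))


@dataclass
class PatternDistribution:
    """Probabilities over all 2^N pattern codes; ``n_samples`` is 0 for model laws."""

    probs: np.ndarray
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1 or (len(self.probs) & (len(self.probs) - 1)) != 0:
            raise ValueError("probs length must be a power of two")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1 within 1e-12")

    @property
    def n_units(self) -> int:
        return int(np.log2(len(self.probs)))


@dataclass
class FitReport:
    iterations: int
    max_moment_gap: float
    converged: bool
    log_likelihood: float


def empirical_distribution(
    series: BinaryPatternSeries, n_units: int | None = None
) -> PatternDistribution:
    """Relative visit frequency of each pattern code."""
    if series.n_frames == 0:
        raise ValueError("empty pattern series")
    n = series.n_units if n_units is None else n_units
    if series.codes.max(initial=0) >= (1 << n):
        raise ValueError(f"codes exceed 2^{n} - 1")
    counts = np.bincount(series.codes, minlength=1 << n).astype(float)
    return PatternDistribution(probs=counts / counts.sum(), n_samples=series.n_frames)


def energy(pattern: np.ndarray, params: MEMParams) -> float:
    """Energy of a single pattern."""
    s = np.asarray(pattern, dtype=float)
    return float(-(params.h @ s) - 0.5 * s @ params.J @ s)


def pattern_energies(params: MEMParams) -> np.ndarray:
    """Energies of all 2^N patterns in code order."""
    n = params.n_units
    if n > _MAX_ENUM_UNITS:
        raise CapacityError(f"exact enumeration limited to N <= {_MAX_ENUM_UNITS}")
    p = all_patterns(n).astype(float)
    return -(p @ params.h) - 0.5 * np.einsum("ci,ci->c", p @ params.J, p)


def boltzmann(params: MEMParams) -> PatternDistribution:
    """Boltzmann distribution over all 2^N patterns (max-subtracted softmax)."""
    e = pattern_energies(params)
    log_z = logsumexp(-e)
    return PatternDistribution(probs=np.exp(-e - log_z), n_samples=0)


def distribution_moments(dist: PatternDistribution) -> tuple[np.ndarray, np.ndarray]:
    """First moments <sigma_i> and second-moment matrix <sigma_i sigma_j>.

    The returned correlation matrix is symmetric with unit diagonal.
    """
    p = all_patterns(dist.n_units).astype(float)
    means = dist.probs @ p
    corr = (p * dist.probs[:, None]).T @ p
    np.fill_diagonal(corr, 1.0)
    return means, corr


def model_moments(params: MEMParams) -> tuple[np.ndarray, np.ndarray]:
    """Exact moments under the Boltzmann distribution of ``params``."""
    return distribution_moments(boltzmann(params))


def log_likelihood(emp: PatternDistribution, params: MEMParams) -> float:
    """Per-sample expected log-likelihood of the model under ``emp``."""
    e = pattern_energies(params)
    logp = -e - logsumexp(-e)
    mask = emp.probs > 0
    return float(emp.probs[mask] @ logp[mask])


def fit_mem(
    emp: PatternDistribution,
    lr: float = 0.2,
    tol: float = 1e-6,
    max_iter: int = 50_000,
) -> tuple[MEMParams, FitReport]:
    """Fit (h, J) by exact-gradient ascent on the log-likelihood.

    Each iteration enumerates the model distribution and moves the
    parameters along the moment discrepancy:

        h_i  += lr * (<sigma_i>_emp - <sigma_i>_model)
        J_ij += lr * (<sigma_i sigma_j>_emp - <sigma_i sigma_j>_model)

    The ascent stops when the largest absolute moment gap falls below
    ``tol`` or after ``max_iter`` iterations.  The gap increasing for 100
    consecutive iterations raises :class:`FitError` (the remedy is a
    smaller ``lr``).

    Notes
    -----
    Zero-frequency patterns need no smoothing: the likelihood depends on the
    empirical distribution only through its first and second moments, which
    are always finite.  Perfectly saturated moments (|<sigma_i>| = 1 or
    |<sigma_i sigma_j>| = 1) have no finite maximizer; the ascent then runs
    to ``max_iter`` and reports ``converged=False``.
    """
    n = emp.n_units
    if n > _MAX_ENUM_UNITS:
        raise CapacityError(f"exact fitting limited to N <= {_MAX_ENUM_UNITS}")
    p = all_patterns(n).astype(float)
    emp_m, emp_c = distribution_moments(emp)
    h = np.zeros(n)
    J = np.zeros((n, n))
    prev_gap = np.inf
    rising = 0
    gap = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        e = -(p @ h) - 0.5 * np.einsum("ci,ci->c", p @ J, p)
        probs = np.exp(-(e - e.min()))
        probs /= probs.sum()
        m = probs @ p
        c = (p * probs[:, None]).T @ p
        dm = emp_m - m
        dc = emp_c - c
        np.fill_diagonal(dc, 0.0)
        gap = max(np.max(np.abs(dm)), np.max(np.abs(dc)))
        if gap <= tol:
            params = MEMParams(h=h, J=J)
            return params, FitReport(
                iterations=it,
                max_moment_gap=float(gap),
                converged=True,
                log_likelihood=log_likelihood(emp, params),
            )
        if gap >= prev_gap:
            rising += 1
            if rising >= 100:
                raise FitError(
                    f"moment gap increased for {rising} consecutive iterations "
                    f"(gap={gap:.3g}); try a smaller learning rate than {lr}"
                )
        else:
            rising = 0
        prev_gap = gap
        h = h + lr * dm
        J = J + lr * dc
    params = MEMParams(h=h, J=J)
    return params, FitReport(
        iterations=it,
        max_moment_gap=float(gap),
        converged=False,
        log_likelihood=log_likelihood(emp, params),
    )
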