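"""Synthetic data generators: exact Ising samples, Markov-switching
oscillatory BOLD, and multi-subject reliability collections.

All randomness flows from one integer seed through named
``numpy.random.SeedSequence`` sub-streams (one per subject/session), so any
fixture is bit-reproducible from its seed alone.

The oscillator emulates the statistical structure the phase front end
assumes: every network is a sinusoid at a common slow frequency (default
0.05 Hz, inside the conventional 0.009-0.08 Hz BOLD band, sampled at
TR = 0.72 s) whose inter-network phase offsets are set by a latent state
switching according to a known Markov chain, plus white Gaussian noise.
It deliberately omits hemodynamic filtering, 1/f background, and spatial
noise correlations of real BOLD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluate import MeasurementSet
from .io import ScanRecord
from .mem import MEMParams, boltzmann
from .phase import BinaryPatternSeries

#: Two latent states over seven networks with complementary antiphase
#: groupings: state 0 opposes networks {3,4,5,6} to {0,1,2}; state 1
#: opposes {2,3,4} to {0,1,5,6}.  Each state therefore maps to a distinct
#: binarized pattern under the leading-eigenvector sign convention.
DEFAULT_STATE_OFFSETS = np.array(
    [
        [0.0, 0.0, 0.0, np.pi, np.pi, np.pi, np.pi],
        [0.0, 0.0, np.pi, np.pi, np.pi, 0.0, 0.0],
    ]
)

#: Persistent two-state chain: mean dwells of 20 and 12.5 frames (14.4 s and
#: 9 s at TR 0.72 s, typical brain-state visit durations), non-uniform
#: stationary law (0.615, 0.385).
DEFAULT_TRANSITION = np.array([[0.95, 0.05], [0.08, 0.92]])


@dataclass
class GeneratorConfig:
    """Shared configuration for the oscillator and reliability generators."""

    n_units: int = 7
    n_frames: int = 1000
    tr_seconds: float = 0.72
    freq_hz: float = 0.05
    noise_sd: float = 0.25
    state_offsets: np.ndarray = field(
        default_factory=lambda: DEFAULT_STATE_OFFSETS.copy()
    )
    transition: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITION.copy())
    initial: np.ndarray | None = None
    n_subjects: int = 2
    n_sessions: int = 2
    dispersion: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.state_offsets = np.asarray(self.state_offsets, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        if self.state_offsets.shape[1] != self.n_units:
            raise ValueError("state_offsets width must equal n_units")
        s = self.state_offsets.shape[0]
        if self.transition.shape != (s, s):
            raise ValueError("transition must be square over latent states")
        if np.any(self.transition < 0) or not np.allclose(
            self.transition.sum(axis=1), 1.0
        ):
            raise ValueError("transition rows must be stochastic")
        if self.initial is not None:
            self.initial = np.asarray(self.initial, dtype=float)
            if self.initial.shape != (s,) or not np.isclose(self.initial.sum(), 1.0):
                raise ValueError("initial must be a distribution over latent states")


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary law of a row-stochastic matrix (left eigenvector at 1)."""
    transition = np.asarray(transition, dtype=float)
    w, v = np.linalg.eig(transition.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def sample_ising(
    params: MEMParams, n_frames: int, seed: int
) -> BinaryPatternSeries:
    """i.i.d. draws from the exact Boltzmann distribution via inverse CDF."""
    if params.n_units > 15:
        raise ValueError("exact sampling limited to N <= 15")
    dist = boltzmann(params)
    cdf = np.cumsum(dist.probs)
    rng = np.random.default_rng(seed)
    u = rng.random(n_frames)
    codes = np.searchsorted(cdf, u, side="right")
    codes = np.minimum(codes, len(dist.probs) - 1)
    return BinaryPatternSeries.from_codes(codes, params.n_units)


def simulate_markov(
    transition: np.ndarray,
    n_frames: int,
    rng: np.random.Generator,
    initial: np.ndarray | None = None,
) -> np.ndarray:
    """Sample a latent-state path from a finite Markov chain."""
    transition = np.asarray(transition, dtype=float)
    s = transition.shape[0]
    pi0 = stationary_distribution(transition) if initial is None else initial
    cum = np.cumsum(transition, axis=1)
    path = np.empty(n_frames, dtype=np.int64)
    path[0] = rng.choice(s, p=pi0)
    u = rng.random(n_frames - 1)
    for t in range(1, n_frames):
        path[t] = np.searchsorted(cum[path[t - 1]], u[t - 1], side="right")
    return np.minimum(path, s - 1)


def gen_oscillator_bold(
    cfg: GeneratorConfig, seed: int | None = None
) -> tuple[ScanRecord, np.ndarray]:
    """Markov-switching phase-coupled oscillator BOLD.

    Network ``i`` at frame ``t`` (time ``t * TR`` seconds) is

        sin(2 pi f t TR + theta_{z(t), i}) + noise,   noise ~ N(0, noise_sd^2)

    where ``z(t)`` is the latent Markov path.  Returns the scan and the
    ground-truth latent labels for recovery tests.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    path = simulate_markov(cfg.transition, cfg.n_frames, rng, cfg.initial)
    t_sec = np.arange(cfg.n_frames) * cfg.tr_seconds
    base = 2 * np.pi * cfg.freq_hz * t_sec
    data = np.sin(base[:, None] + cfg.state_offsets[path]) + rng.normal(
        0.0, cfg.noise_sd, size=(cfg.n_frames, cfg.n_units)
    )
    scan = ScanRecord(
        data=data,
        region_labels=[f"net{i + 1}" for i in range(cfg.n_units)],
        tr_seconds=cfg.tr_seconds,
        condition="synthetic",
    )
    return scan, path


def gen_reliability_set(
    n_subjects: int,
    n_sessions: int,
    n_states: int = 4,
    n_frames: int = 2000,
    dispersion: float = 1.0,
    seed: int = 0,
) -> MeasurementSet:
    """Multi-subject, multi-session occupancy features for reliability tests.

    Each subject receives its own latent-state preference vector
    ``b ~ N(0, dispersion^2)`` drawn once, defining a state distribution
    ``softmax(b)``; each session is a fresh realization of ``n_frames``
    latent draws, and its feature row is the empirical state occupancy.
    ``dispersion = 0`` makes all subjects share the uniform distribution
    (features exchangeable across subjects, MNR near 0.5); large dispersion
    with long sessions separates subjects cleanly (MNR toward 1).
    """
    if n_subjects < 2 or n_sessions < 2:
        raise ValueError("need n_subjects >= 2 and n_sessions >= 2")
    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(n_subjects)
    features = []
    subject_of: list[str] = []
    session_of: list[str] = []
    for s, sub_seq in enumerate(subject_seeds):
        streams = sub_seq.spawn(n_sessions + 1)
        rng_sub = np.random.default_rng(streams[0])
        b = rng_sub.normal(0.0, dispersion, n_states) if dispersion > 0 else np.zeros(
            n_states
        )
        p = np.exp(b - b.max())
        p /= p.sum()
        for sess in range(n_sessions):
            rng_sess = np.random.default_rng(streams[sess + 1])
            counts = rng_sess.multinomial(n_frames, p)
            features.append(counts / n_frames)
            subject_of.append(f"sub{s:03d}")
            session_of.append(f"ses{sess:02d}")
    return MeasurementSet(
        features=np.array(features),
        subject_of=subject_of,
        session_of=session_of,
        feature_names=[f"state{i}" for i in range(n_states)],
    )
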