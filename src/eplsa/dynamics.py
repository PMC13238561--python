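"""Brain-state dynamics: occupancy, dwell time, transitions, major/minor split.

A pattern time series is mapped through the landscape's basins onto a
state sequence (one state per local minimum).  The dynamics of the states
are summarized by fractional occupancy (share of frames per state), dwell
time (mean contiguous visit duration, seconds), occurrence frequency
(visits per second), and a transition matrix.  States are further split
into major and minor groups by basin size, and major-to-major excursions
are classified as direct (no intervening state) or indirect (mediated by
minor states only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .landscape import Landscape
from .phase import BinaryPatternSeries

logger = logging.getLogger(__name__)


@dataclass
class StateSequence:
    """Per-frame state labels with run-length encoding."""

    labels: np.ndarray
    tr_seconds: float = 1.0
    n_states: int | None = None
    runs: list[tuple[int, int, int]] = field(default_factory=list)  # (state, start, length)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or len(self.labels) == 0:
            raise ValueError("labels must be a nonempty 1-D vector")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_states is None:
            self.n_states = int(self.labels.max()) + 1
        if not self.runs:
            self.runs = _run_length_encode(self.labels)

    @property
    def n_frames(self) -> int:
        return len(self.labels)


def _run_length_encode(labels: np.ndarray) -> list[tuple[int, int, int]]:
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [len(labels)])))
    return [
        (int(labels[s]), int(s), int(l)) for s, l in zip(starts, lengths)
    ]


def label_states(
    patterns: BinaryPatternSeries, landscape: Landscape, tr_seconds: float = 1.0
) -> StateSequence:
    """Map each frame's pattern code to the state of its attractor basin."""
    if patterns.n_units != landscape.n_units:
        raise ValueError("pattern width does not match landscape")
    labels = landscape.state_of(patterns.codes)
    return StateSequence(
        labels=labels, tr_seconds=tr_seconds, n_states=landscape.n_states
    )


@dataclass
class StateMetrics:
    """Occupancy, dwell, occurrence frequency, and transitions per state.

    ``dwell_time`` is NaN for unvisited states; transition rows with no
    observed exit are NaN and flagged in ``undefined_rows``.
    """

    fractional_occupancy: np.ndarray
    dwell_time: np.ndarray  # seconds
    dwell_frames: np.ndarray
    occurrence_frequency: np.ndarray  # runs per second
    transition_matrix: np.ndarray
    transition_counts: np.ndarray
    undefined_rows: np.ndarray
    include_self: bool
    tr_seconds: float


def state_metrics(
    seq: StateSequence, include_self: bool = False
) -> StateMetrics:
    """Summarize a state sequence.

    Parameters
    ----------
    seq:
        Labeled frame sequence.
    include_self:
        If False (default) the transition matrix counts only state changes,
        i.e. consecutive runs, and rows are normalized over observed exits.
        If True it counts all frame-adjacent label pairs, giving the
        Markov-chain transition matrix including self-transitions.
    """
    n = seq.n_states
    t = seq.n_frames
    occupancy = np.bincount(seq.labels, minlength=n).astype(float) / t
    run_states = np.array([r[0] for r in seq.runs])
    run_lengths = np.array([r[2] for r in seq.runs])
    dwell_frames = np.full(n, np.nan)
    n_runs = np.zeros(n)
    for s in range(n):
        mask = run_states == s
        n_runs[s] = mask.sum()
        if mask.any():
            dwell_frames[s] = run_lengths[mask].mean()
    duration = t * seq.tr_seconds
    counts = np.zeros((n, n))
    if include_self:
        for a, b in zip(seq.labels[:-1], seq.labels[1:]):
            counts[a, b] += 1
    else:
        for a, b in zip(run_states[:-1], run_states[1:]):
            counts[a, b] += 1
    row_sums = counts.sum(axis=1)
    undefined = row_sums == 0
    matrix = np.full((n, n), np.nan)
    visited = ~undefined
    matrix[visited] = counts[visited] / row_sums[visited, None]
    return StateMetrics(
        fractional_occupancy=occupancy,
        dwell_time=dwell_frames * seq.tr_seconds,
        dwell_frames=dwell_frames,
        occurrence_frequency=n_runs / duration,
        transition_matrix=matrix,
        transition_counts=counts,
        undefined_rows=undefined,
        include_self=include_self,
        tr_seconds=seq.tr_seconds,
    )


@dataclass
class MajorMinorSplit:
    """Partition of states into major and minor groups, with the rule applied."""

    major: set[int]
    minor: set[int]
    rule: str

    def __post_init__(self) -> None:
        if not self.major:
            raise ValueError("major set must be nonempty")
        if self.major & self.minor:
            raise ValueError("major and minor sets overlap")


def split_major_minor(
    landscape_or_sizes,
    rule: str = "above-uniform",
    k: int | None = None,
    members: set[int] | None = None,
) -> MajorMinorSplit:
    """Classify states as major or minor from basin sizes.

    Rules
    -----
    ``above-uniform`` (default):
        major iff basin size strictly exceeds the uniform share 1/n_states.
    ``top-k``:
        the ``k`` largest basins (ties toward the smaller state index).
    ``explicit``:
        ``members`` gives the major set directly.

    An empty major set (e.g. all basins exactly equal under the default
    rule) falls back to the single largest basin and is logged.
    """
    sizes = (
        landscape_or_sizes.basin_size
        if isinstance(landscape_or_sizes, Landscape)
        else np.asarray(landscape_or_sizes, dtype=float)
    )
    n = len(sizes)
    states = set(range(n))
    if rule == "above-uniform":
        major = {i for i in range(n) if sizes[i] > 1.0 / n}
        desc = f"above-uniform (size > 1/{n})"
    elif rule == "top-k":
        if k is None or not (1 <= k <= n):
            raise ValueError("top-k rule needs 1 <= k <= n_states")
        order = np.lexsort((np.arange(n), -sizes))
        major = set(int(i) for i in order[:k])
        desc = f"top-{k} basins"
    elif rule == "explicit":
        if not members or not set(members) <= states:
            raise ValueError("explicit rule needs a nonempty subset of states")
        major = set(members)
        desc = f"explicit {sorted(major)}"
    else:
        raise ValueError(f"unknown split rule {rule!r}")
    if not major:
        fallback = int(np.argmax(sizes))
        logger.warning(
            "split rule %r selected no major state; falling back to the "
            "largest basin (state %d)",
            rule,
            fallback,
        )
        major = {fallback}
        desc += " [fallback: largest basin]"
    return MajorMinorSplit(major=major, minor=states - major, rule=desc)


@dataclass
class TransitionSplit:
    """Counts and probabilities of direct vs. minor-mediated major transitions."""

    direct: int
    indirect: int
    direct_prob: float
    indirect_prob: float
    pair_counts: dict[tuple[int, int], dict[str, int]]


def direct_indirect(seq: StateSequence, split: MajorMinorSplit) -> TransitionSplit:
    """Classify every excursion between consecutive major-state runs.

    The sequence is collapsed to its run sequence.  An excursion between
    two consecutive major runs with no intervening run is *direct*; one
    whose intervening runs are all minor is *indirect* (by construction any
    non-major run is minor, so every excursion falls in one class).
    Probabilities are normalized over all excursions; per-ordered-pair
    counts are returned alongside.  A sequence with fewer than two major
    runs yields zero counts and NaN probabilities.
    """
    run_states = [r[0] for r in seq.runs]
    major_positions = [i for i, s in enumerate(run_states) if s in split.major]
    direct = indirect = 0
    pair_counts: dict[tuple[int, int], dict[str, int]] = {}
    for prev, nxt in zip(major_positions[:-1], major_positions[1:]):
        kind = "direct" if nxt == prev + 1 else "indirect"
        if kind == "direct":
            direct += 1
        else:
            indirect += 1
        pair = (run_states[prev], run_states[nxt])
        pair_counts.setdefault(pair, {"direct": 0, "indirect": 0})[kind] += 1
    total = direct + indirect
    if total == 0:
        return TransitionSplit(0, 0, float("nan"), float("nan"), pair_counts)
    p_direct = direct / total
    return TransitionSplit(direct, indirect, p_direct, 1.0 - p_direct, pair_counts)
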