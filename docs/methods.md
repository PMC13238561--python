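# Methods

## Phase front end

Each column (ROI or network) is demeaned and Hilbert-transformed; the
instantaneous phase is the quadrant-aware angle of the analytic signal,
wrapped into (−π, π]. No filtering is applied — inputs are assumed
band-limited upstream, as is standard for BOLD preprocessing. Because the
analytic signal is computed by FFT over the whole record, the first and
last `trim` frames (default 1 per end, configurable) are flagged invalid to
absorb edge effects; pipeline outputs cover only the valid range.

The dynamic phase-locking matrix at frame t is cos(φ_i − φ_j): symmetric,
unit diagonal, entries in [−1, 1]. Its leading eigenvector is computed by a
deterministic symmetric eigensolver. An eigenvector is defined only up to
global sign, so a fixed orientation is imposed before binarization: the
vector is flipped so that strictly more components are negative than
positive, a zero component counting as negative; on an exact tie the
largest-magnitude component (first such index, in canonical unit order) is
made non-positive. This matches the community-splitting convention used in
leading-eigenvector analyses and makes binarization (> 0 → +1 active,
≤ 0 → −1 inactive) deterministic, including for degenerate leading
eigenvalues. Binarization at zero requires no tuned threshold: the split
reflects the bipartite phase structure of the eigenvector itself.

Patterns are encoded as integers in [0, 2^N) with +1 → bit 1 and unit 0 as
the most significant bit; decoding is exact for all N ≤ 24.

## Pairwise maximum-entropy model

Energy of a pattern σ ∈ {−1,+1}^N:

    E(σ | h, J) = − Σᵢ hᵢ σᵢ − ½ Σ_{i≠j} Jᵢⱼ σᵢ σⱼ,

with J symmetric and zero-diagonal; P(σ) ∝ exp(−E). h is the basal
activity of a unit; J the pairwise interaction. The maximum-entropy
conditions equate model and empirical first and second moments, which is
exactly the stationarity condition of the log-likelihood; fitting is plain
gradient ascent with *exact* model moments from full 2^N enumeration:

    hᵢ  ← hᵢ  + lr (⟨σᵢ⟩_emp − ⟨σᵢ⟩_mod),
    Jᵢⱼ ← Jᵢⱼ + lr (⟨σᵢσⱼ⟩_emp − ⟨σᵢσⱼ⟩_mod).

Defaults: lr = 0.2, tol = 1e−6 on the max absolute moment gap,
max_iter = 50 000, zero initialization. The objective is concave, so with a
sufficiently small step the gap decreases; a gap rising for 100 consecutive
iterations aborts with advice to lower lr. Two practical regimes:

- Generic data (moments well inside (−1, 1)): convergence in a few hundred
  iterations at the default lr; parameter recovery from 10^5 exact samples
  of a ground-truth model with entries in (−0.5, 0.5) is accurate to ~0.01.
- Near-saturated moments (e.g. a series dominated by two complementary
  patterns): the maximizer lies at infinity in some directions. lr = 0.2
  overshoots and triggers the divergence guard; lr = 0.05 proceeds stably
  but stops at max_iter with a small residual gap and `converged=False`.
  Energies then contain some large entries, but the ranking of
  low-energy patterns — hence minima, basins, and state labels — is stable.

Zero-frequency patterns need no smoothing: only the moments enter the fit,
and the model distribution is strictly positive regardless. Group-level
fits pool pattern frames across scans before computing the empirical
distribution; per-scan fits are equally supported.

Exact enumeration bounds the practical range to roughly 6–15 units; the
canonical use is N = 7 functional networks (128 patterns).

## Energy landscape

Patterns form an N-dimensional hypercube graph (adjacency = single-unit
flip). A local minimum has strictly lower energy than all N neighbors.
Because P is monotone decreasing in E, "most frequent in its
neighborhood" and "lowest energy in its neighborhood" define the same
states.

Basins are assigned by steepest descent: from any pattern, repeatedly move
to the lowest-energy neighbor until a minimum is reached. Ties (two
neighbors sharing the minimal energy) break toward the smallest pattern
code; a plateau (equal-energy neighbor, none lower) moves to the
smallest-code equal neighbor and is logged as a degenerate landscape. Both
tie cases have measure zero for continuously fitted parameters; the fixed
total order exists purely for determinism. Basin size is the fraction of
the 2^N patterns draining to the minimum.

Barriers: the barrier between two minima is the minimax path cost on the
hypercube (the lowest over paths of the highest energy en route). This is
exactly what the classical threshold-lowering construction computes —
remove all patterns with energy ≥ E_th, lower E_th through the sorted
energy values, and record where each pair of minima disconnects. The
implementation runs the sweep bottom-up with a union-find (activate
patterns in ascending energy; when two components each holding minima
join at pattern v, every cross pair's barrier is E(v)), which is
O(2^N α(2^N)) and provably identical to literal node removal; tests verify
exact equality against an independent Dijkstra-style bottleneck-path
oracle. Barriers form an ultrametric, so the single-linkage tree over them
is exact: the disconnectivity tree has leaves at minima energies and
internal nodes at merge (barrier) energies, exported as Newick with branch
lengths = parent height − child height and leaf names `<code>_<bits>`.

## State dynamics

Frames map to states through the basin of their pattern code. Metrics:
fractional occupancy (frames in state / total frames), dwell time (mean
contiguous run length × TR, seconds), occurrence frequency (runs per
second), and a transition matrix. By default the matrix counts only state
*changes* (consecutive runs, rows normalized over observed exits), since
inter-state transition structure is usually the quantity of interest; an
`include_self` flag switches to the frame-level Markov matrix. Rows of
unvisited or exit-less states are NaN and flagged rather than silently
zeroed.

Major/minor split: the default rule marks a state major when its basin
size exceeds the uniform share 1/n_states; top-k and explicit lists are
also available, and the applied rule is recorded in the output. The
above-uniform default is a package choice — there is no canonical rule —
and an empty major set falls back to the single largest basin (logged).
Direct vs. indirect transitions: collapse the sequence to runs; each
excursion between consecutive major runs is direct (no intervening run)
or indirect (only minor runs intervene). Probabilities are normalized over
all excursions, with per-ordered-pair counts exposed for finer analyses.

## Baselines

LEiDA: k-means (scikit-learn, Euclidean distance, `n_init` restarts from a
mandatory seed) over the same sign-fixed leading eigenvectors, at ROI or
network level. On unit-norm vectors Euclidean distance is monotone in
cosine distance, so the choice is innocuous and is recorded in outputs.
Sign-fixing before clustering prevents antipodal splitting of one
phase-locking state into two clusters. Centroids are means of sign-fixed
members and inherit the orientation; they are not re-flipped afterwards,
which could break the nearest-centroid property. Cluster quality: Dunn
index = min inter-cluster point distance / max intra-cluster diameter
(+inf flag for zero-diameter clusters), and distortion = k-means inertia.

Amplitude ELA: per-column z-score, then sign threshold at 0 (the column
mean); configurable absolute threshold. The resulting pattern series feeds
the identical MEM/landscape/dynamics machinery, so the phase and amplitude
front ends are compared on equal footing. All three methods emit the same
per-frame label interface.

## Evaluation statistics

MNR discriminability: for each ordered within-subject pair (i, j), the
distance D[i,j] is ranked against row i's between-subject distances
(same-subject distances excluded by masking),
r = 1 − [#(below) + 0.5·#(ties)] / (N − S); MNR is the mean over pairs.
1 = perfectly reliable, 0.5 = exchangeable. Rank-based, hence invariant to
any strictly increasing transform of distances.

Symmetrized KL between occupancy distributions:
0.5·[Σ P ln(P/Q) + Σ Q ln(Q/P)], with additive smoothing (eps = 1e−10,
then renormalization) applied only when either distribution has zeros —
unavoidable when a state goes unvisited in one condition. The pairwise
driver emits all C(k, 2) unordered condition comparisons.

`occupancy_features` exports per-scan occurrence-frequency rows with
subject/session/condition metadata — the exact feature table an external
classifier consumes; classification itself is out of scope.

## Synthetic generators

All randomness derives from one integer seed through named
`SeedSequence` sub-streams per subject/session, so fixtures are
bit-reproducible.

- `sample_ising`: inverse-CDF draws from the exactly enumerated Boltzmann
  distribution (N ≤ 15).
- `gen_oscillator_bold`: every network is sin(2π f t + θ) + N(0, σ²) with
  the offset vector θ selected by a latent Markov chain. Defaults:
  f = 0.05 Hz, TR = 0.72 s (inside the conventional 0.009–0.08 Hz band),
  noise σ = 0.25, and a persistent two-state chain with stay probabilities
  (0.95, 0.92): mean dwells 14.4 s and 9 s, typical of reported
  brain-state durations, and stationary law (8/13, 5/13). The two default
  offset vectors are complementary antiphase partitions of 7 networks, so
  each latent state maps to a distinct binarized pattern (codes 112
  and 28). Dwells must comfortably exceed the few-frame Hilbert transient
  that follows each offset jump; at much shorter dwells (≲3 frames) the
  transient blurs a substantial share of each visit. The generator omits
  hemodynamic convolution, 1/f background, and spatially correlated noise,
  so passing recovery tests demonstrates correctness of the machinery on
  phase-switching dynamics, not robustness to all properties of real BOLD.
- `gen_reliability_set`: each subject draws a state-preference vector
  b ~ N(0, dispersion²) once; session features are empirical occupancies of
  n_frames i.i.d. latent draws from softmax(b) (a constant-row Markov
  chain). dispersion = 0 makes subjects exchangeable (MNR ≈ 0.5); large
  dispersion with long sessions separates them (MNR → 1).

### Recovery-test design

Estimated state sequences are compared to the latent ground truth after
majority-vote matching (each estimated state maps to the latent state
holding most of its frames), the standard correspondence when spurious
transition-frame basins can outnumber true states. Occupancy is compared
to the *realized* latent occupancy of the simulated path: for a persistent
chain the realized occupancy itself fluctuates around the stationary law
with variance inflated by (1+ρ)/(1−ρ) relative to i.i.d. sampling
(ρ ≈ 0.87 at the default chain), so the realized path — not the stationary
vector — is the correct reference for what the estimator can see. The
binomial standard error then bounds only the labeling error, which is the
quantity under test.

## Problem sizes and numerical choices

Tests and the acceptance script run at N = 7 networks (N = 4–6 for
brute-force oracle comparisons), 10^4-frame oscillator recoveries, 10^5
exact Ising samples for parameter recovery, and 200 replicates for the
exchangeability endpoint — sizes at which every stochastic check has
comfortable margin while the full suite completes in seconds. Boltzmann
probabilities are computed with max-subtraction; barrier sweeps break
energy ties by pattern code; validation tolerances are 1e−10 for matrix
symmetry and 1e−12 for distribution normalization.

## Known limitations

- Exact enumeration limits the model to ~15 units; no pseudo-likelihood or
  MCMC path for larger N.
- Only the leading eigenvector is retained per frame; secondary
  synchronization modes are discarded.
- The landscape is built from a point estimate of (h, J); no uncertainty
  on energies or barriers is propagated.
- Network aggregation is the unweighted mean of member ROI columns;
  volume-weighted averaging is not implemented.
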