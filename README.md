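# eplsa

Energy-based phase-locking state analysis of network BOLD dynamics.

Resting and task fMRI activity wanders between a small repertoire of
recurrent whole-brain configurations. Two families of methods describe this:
phase-based ones (LEiDA) that track instantaneous synchronization between
networks but offer no notion of state stability, and energy-landscape
analysis (ELA) that gives states a thermodynamic depth but works only on
signal amplitudes. `eplsa` combines the two: it builds an energy landscape
on *phase-locking* patterns, so each brain state is an attractor basin with
a depth and barriers, while the states themselves are defined by
inter-network synchronization rather than amplitude.

## Who this is for

Researchers with preprocessed ROI- or network-level BOLD time series
(plain CSV/TSV tables) who want phase-based brain states with energies,
basins, barrier structure, and occupancy/dwell/transition statistics — plus
the standard baselines (LEiDA k-means, amplitude ELA) and evaluation
statistics (discriminability, occupancy divergence) to compare methods.

## The method

1. **Phase front end.** Each network series is demeaned and
   Hilbert-transformed; the instantaneous phase φ_j(t) is the angle of the
   analytic signal. Pairwise synchrony at frame t is the dynamic
   phase-locking matrix dPL(i,j,t) = cos(φ_i(t) − φ_j(t)). The leading
   eigenvector V₁(t) of each dPL matrix captures the dominant
   synchronization mode; its components are binarized at zero
   (sign-fixed so the larger phase community is negative), giving a binary
   activity pattern σ(t) ∈ {−1,+1}^N per frame.

2. **Pairwise maximum-entropy model.** The empirical pattern distribution
   is fitted by the Boltzmann distribution P(σ) ∝ exp(−E(σ)) with

       E(σ | h, J) = − Σᵢ hᵢσᵢ − ½ Σ_{i≠j} Jᵢⱼ σᵢσⱼ,

   the least-structured distribution matching the first and second moments
   ⟨σᵢ⟩ and ⟨σᵢσⱼ⟩. Fitting is exact-gradient ascent with full enumeration
   of the 2^N patterns (N ≤ ~15, N = 7 canonical networks typical).

3. **Energy landscape.** Local minima of E on the pattern hypercube are the
   brain states; every pattern is assigned to a basin by steepest descent;
   barriers between minima are minimax path costs, summarized as a
   disconnectivity tree (Newick export).

4. **Dynamics.** Frame sequences map to basin sequences, yielding
   fractional occupancy, dwell times, occurrence frequencies, transition
   matrices, a major/minor state split by basin size, and direct vs.
   minor-mediated transition probabilities between major states.

Evaluation tools include the mean-nearest-rank (MNR) discriminability
index for test-retest reliability and the symmetrized Kullback–Leibler
divergence between condition-wise occupancy distributions. A synthetic
module generates exact Ising samples, Markov-switching oscillator BOLD
with ground-truth latent states, and multi-subject reliability sets.

## Worked example

```python
import numpy as np
from eplsa import (GeneratorConfig, gen_oscillator_bold, phase_pipeline,
                   empirical_distribution, fit_mem, landscape_from_params,
                   label_states, state_metrics, split_major_minor,
                   direct_indirect)

cfg = GeneratorConfig(n_frames=3000, seed=42)   # 2 latent states, TR 0.72 s
scan, latent = gen_oscillator_bold(cfg)
series = phase_pipeline(scan, trim=10)
params, report = fit_mem(empirical_distribution(series), lr=0.05, max_iter=10_000)
ls = landscape_from_params(params)
seq = label_states(series, ls, tr_seconds=cfg.tr_seconds)
m = state_metrics(seq)
split = split_major_minor(ls)
di = direct_indirect(seq, split)

print(ls.minima.tolist())               # [112, 28, 98, 13, 14]
print(np.round(ls.basin_size, 3))       # [0.336 0.281 0.164 0.156 0.062]
print(np.round(m.fractional_occupancy, 3))  # [0.599 0.381 0.007 0.007 0.006]
print(np.round(m.dwell_time, 2))        # [12.48  9.28  0.79  0.72  0.72] seconds
print(sorted(split.major), round(di.direct_prob, 3))  # [0, 1] 0.716
```

The two deepest minima are the pattern codes 112 = (+,+,+,−,−,−,−) and
28 = (−,−,+,+,+,−,−): exactly the antiphase partitions of the generator's
two latent states. Their occupancies (0.599, 0.381) track the latent
chain's stationary law (0.615, 0.385); the remaining three shallow states
are brief transition configurations (sub-second dwell), and 71.6% of
major-state changes happen directly rather than through a minor state.
(`report.converged` is `False` here: the near-saturated moments of a
two-state oscillator drive couplings toward large values, so the moment gap
at stop is ~1e−3 — the landscape and minima are unaffected.)

The same pipeline runs from the shell:

```sh
eplsa --seed 1 simulate bold --n-frames 3000 --out scan.csv
eplsa phases --input scan.csv --trim 10 --tr 0.72 --out patterns.tsv
eplsa fit-mem --patterns patterns.tsv --lr 0.05 --out mem.json
eplsa landscape --mem mem.json --out landscape.json --newick tree.nwk
eplsa dynamics --patterns patterns.tsv --landscape landscape.json --tr 0.72 --out metrics.tsv
```

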