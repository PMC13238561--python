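"""Independent oracles and shared generators for the test suite.

Everything here is deliberately written from scratch (brute force,
priority-queue search) so it cannot share a bug with the implementation
it checks.
"""

from __future__ import annotations

import heapq

import numpy as np


def random_landscape(n_units: int, rng: np.random.Generator) -> np.ndarray:
    """Continuous random energies over 2^N patterns (ties measure zero)."""
    return rng.normal(0.0, 1.0, 1 << n_units)


def brute_minima(energies: np.ndarray, n_units: int) -> list[int]:
    """Exhaustive neighbor check, double loop."""
    out = []
    for c in range(1 << n_units):
        if all(energies[c] < energies[c ^ (1 << k)] for k in range(n_units)):
            out.append(c)
    out.sort(key=lambda c: (energies[c], c))
    return out


def brute_descent_labels(energies: np.ndarray, n_units: int) -> np.ndarray:
    """Fresh steepest-descent walk from every start, no memoization.

    Tie rule identical to the implementation: move to the lowest-energy
    neighbor, smallest code on ties.
    """
    size = 1 << n_units
    labels = np.empty(size, dtype=np.int64)
    for start in range(size):
        cur = start
        for _ in range(size + 1):
            nbrs = [cur ^ (1 << k) for k in range(n_units)]
            best = min(energies[u] for u in nbrs)
            if best >= energies[cur]:
                break
            cur = min(u for u in nbrs if energies[u] == best)
        labels[start] = cur
    return labels


def bottleneck_barrier(energies: np.ndarray, n_units: int, a: int, b: int) -> float:
    """Minimax path cost a -> b on the hypercube via Dijkstra on max-so-far.

    The cost of a path is the maximum node energy along it (endpoints
    included); the barrier is the minimum over all paths.
    """
    size = 1 << n_units
    best = np.full(size, np.inf)
    heap = [(energies[a], a)]
    best[a] = energies[a]
    while heap:
        cost, node = heapq.heappop(heap)
        if node == b:
            return cost
        if cost > best[node]:
            continue
        for k in range(n_units):
            nxt = node ^ (1 << k)
            c = max(cost, energies[nxt])
            if c < best[nxt]:
                best[nxt] = c
                heapq.heappush(heap, (c, nxt))
    raise RuntimeError("hypercube is connected; unreachable")
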