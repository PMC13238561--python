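"""Energy landscape over the pattern hypercube: minima, basins, disconnectivity.

Patterns live on the N-dimensional hypercube graph (two codes adjacent iff
they differ at exactly one unit).  A *local minimum* has strictly lower
energy than all N single-flip neighbors and operationalizes a brain state.
Every pattern is assigned to the basin of the minimum reached by steepest
descent, and the *barrier* between two minima is the minimax path cost on
the hypercube — equivalently the lowest energy threshold at which the two
minima remain connected when all patterns at or above the threshold are
removed.  Barriers form an ultrametric and are summarized as a
disconnectivity tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mem import MEMParams, pattern_energies
from .phase import decode_codes

logger = logging.getLogger(__name__)


class CycleError(RuntimeError):
    """Raised if a descent walk fails to terminate (corrupted energies)."""


def _check_energies(energies: np.ndarray, n_units: int) -> np.ndarray:
    energies = np.asarray(energies, dtype=float)
    if energies.shape != (1 << n_units,):
        raise ValueError(f"expected {1 << n_units} energies for N={n_units}")
    if not np.all(np.isfinite(energies)):
        raise ValueError("energies must be finite")
    return energies


def neighbor_codes(codes: np.ndarray, n_units: int) -> np.ndarray:
    """Single-flip (Hamming-distance-1) neighbors; shape (..., N)."""
    codes = np.asarray(codes, dtype=np.int64)
    return codes[..., None] ^ (1 << np.arange(n_units))


def find_minima(energies: np.ndarray, n_units: int) -> np.ndarray:
    """Codes with strictly lower energy than every neighbor, energy-ascending."""
    energies = _check_energies(energies, n_units)
    codes = np.arange(1 << n_units)
    nbr = neighbor_codes(codes, n_units)
    is_min = np.all(energies[:, None] < energies[nbr], axis=1)
    minima = codes[is_min]
    order = np.lexsort((minima, energies[minima]))
    return minima[order]


def assign_basins(
    energies: np.ndarray, minima: np.ndarray, n_units: int
) -> np.ndarray:
    """Steepest-descent basin label (the terminal minimum's code) per pattern.

    From each pattern the walk moves to the strictly-lowest-energy neighbor
    (ties broken toward the smallest code) until a minimum is reached.  A
    plateau step — no strictly lower neighbor on a non-minimum — moves to
    the smallest-code equal-energy neighbor and is logged as a degenerate
    landscape; such ties have measure zero for fitted continuous parameters.
    """
    energies = _check_energies(energies, n_units)
    size = 1 << n_units
    minima_set = set(int(m) for m in minima)
    label = np.full(size, -1, dtype=np.int64)
    bits = 1 << np.arange(n_units)
    plateau_warned = False
    for start in range(size):
        if label[start] >= 0:
            continue
        path: list[int] = []
        cur = start
        while label[cur] < 0:
            if cur in minima_set:
                label[cur] = cur
                break
            path.append(cur)
            if len(path) > size:
                raise CycleError("descent walk exceeded 2^N steps")
            nbrs = cur ^ bits
            e_n = energies[nbrs]
            best = e_n.min()
            if best < energies[cur]:
                cur = int(nbrs[e_n == best].min())
            elif best == energies[cur]:
                if not plateau_warned:
                    logger.warning(
                        "degenerate landscape: plateau at code %d "
                        "(equal-energy neighbor, none lower)",
                        cur,
                    )
                    plateau_warned = True
                cur = int(nbrs[e_n == best].min())
            else:
                # strictly lower than all neighbors yet not in the minima list
                raise ValueError(
                    f"code {cur} is a strict local minimum absent from `minima`"
                )
        label[path] = label[cur]
    return label


def basin_sizes(basin_label: np.ndarray, minima: np.ndarray) -> np.ndarray:
    """Fraction of the 2^N patterns in each minimum's basin (sums to 1)."""
    basin_label = np.asarray(basin_label)
    sizes = np.array([(basin_label == m).sum() for m in minima], dtype=float)
    total = len(basin_label)
    if sizes.sum() != total:
        raise ValueError("basin labels refer to codes outside `minima`")
    return sizes / total


@dataclass
class TreeNode:
    """Node of a disconnectivity tree; leaves carry minima, internal nodes merge energies."""

    height: float
    code: int | None = None  # set on leaves only
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.code is not None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class DisconnectivityTree:
    root: TreeNode
    n_units: int

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge energy minus child height.

        Leaf names are ``<code>_<bits>`` with bit 1 for an active (+1) unit,
        unit 0 first.
        """

        def name(node: TreeNode) -> str:
            bits = "".join(
                "1" if s > 0 else "0" for s in decode_codes(node.code, self.n_units)[0]
            )
            return f"{node.code}_{bits}"

        def render(node: TreeNode, parent_height: float | None) -> str:
            if node.is_leaf:
                text = name(node)
            else:
                inner = ",".join(render(c, node.height) for c in node.children)
                text = f"({inner})"
            if parent_height is None:
                return text
            return f"{text}:{parent_height - node.height:.10g}"

        return render(self.root, None) + ";"


class _DisjointSet:
    def __init__(self, n: int) -> None:
        self.parent = np.arange(n, dtype=np.int64)

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = int(self.parent[root])
        while self.parent[x] != root:
            self.parent[x], x = root, int(self.parent[x])
        return root

    def union(self, a: int, b: int) -> tuple[int, int]:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra
        return ra, rb


def disconnectivity(
    energies: np.ndarray, minima: np.ndarray, n_units: int
) -> tuple[DisconnectivityTree, np.ndarray]:
    """Pairwise barrier matrix between minima and the disconnectivity tree.

    Implemented as an offline union-find sweep over patterns in ascending
    energy order: activating patterns from low to high energy and joining
    hypercube-adjacent active components reproduces, level by level, the
    connectivity obtained by lowering the removal threshold from the top —
    the two minima of a newly joined pair first connect exactly at the
    energy of the activated pattern, which is their minimax path cost.

    Barriers satisfy ``barrier(a, a) = E(a)`` and the ultrametric inequality
    ``barrier(a, c) <= max(barrier(a, b), barrier(b, c))``.
    """
    energies = _check_energies(energies, n_units)
    minima = np.asarray(minima, dtype=np.int64)
    if len(minima) == 0:
        raise ValueError("need at least one minimum")
    m = len(minima)
    barriers = np.zeros((m, m))
    np.fill_diagonal(barriers, energies[minima])
    idx_of = {int(c): i for i, c in enumerate(minima)}
    size = 1 << n_units
    codes = np.arange(size)
    # stable ascending sweep; ties broken by code for determinism
    order = np.lexsort((codes, energies))
    dsu = _DisjointSet(size)
    active = np.zeros(size, dtype=bool)
    comp_minima: dict[int, list[int]] = {}
    comp_node: dict[int, TreeNode] = {}
    bits = 1 << np.arange(n_units)
    for v in order:
        v = int(v)
        active[v] = True
        root_v = v
        if v in idx_of:
            leaf = TreeNode(height=float(energies[v]), code=v)
            comp_minima[root_v] = [idx_of[v]]
            comp_node[root_v] = leaf
        for u in v ^ bits:
            u = int(u)
            if not active[u]:
                continue
            ra, rb = dsu.find(v), dsu.find(u)
            if ra == rb:
                continue
            mins_a = comp_minima.pop(ra, None)
            mins_b = comp_minima.pop(rb, None)
            node_a = comp_node.pop(ra, None)
            node_b = comp_node.pop(rb, None)
            new_root, _ = dsu.union(ra, rb)
            if mins_a and mins_b:
                for a in mins_a:
                    for b in mins_b:
                        barriers[a, b] = barriers[b, a] = energies[v]
                merged = TreeNode(
                    height=float(energies[v]), children=[node_a, node_b]
                )
                comp_minima[new_root] = mins_a + mins_b
                comp_node[new_root] = merged
            elif mins_a or mins_b:
                comp_minima[new_root] = mins_a or mins_b
                comp_node[new_root] = node_a if node_a is not None else node_b
    roots = {dsu.find(int(c)) for c in minima}
    if len(roots) != 1:  # hypercube is connected, so this cannot happen
        raise RuntimeError("minima ended in disjoint components")
    tree = DisconnectivityTree(root=comp_node[roots.pop()], n_units=n_units)
    return tree, barriers


@dataclass
class Landscape:
    """Full landscape bundle: energies, minima, basins, barriers, tree."""

    energies: np.ndarray
    minima: np.ndarray
    basin_label: np.ndarray  # per pattern, the code of its terminal minimum
    basin_size: np.ndarray  # fractions, aligned with `minima`
    barriers: np.ndarray
    tree: DisconnectivityTree

    @property
    def n_units(self) -> int:
        return int(np.log2(len(self.energies)))

    @property
    def n_states(self) -> int:
        return len(self.minima)

    def state_of(self, codes: np.ndarray) -> np.ndarray:
        """Map pattern codes to state indices (positions in ``minima``)."""
        idx = {int(c): i for i, c in enumerate(self.minima)}
        return np.array([idx[int(m)] for m in self.basin_label[np.asarray(codes)]])

    def to_dict(self) -> dict:
        return {
            "n_units": self.n_units,
            "energies": self.energies.tolist(),
            "minima": self.minima.tolist(),
            "basin_label": self.basin_label.tolist(),
            "basin_size": self.basin_size.tolist(),
            "barriers": self.barriers.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Landscape":
        energies = np.array(d["energies"], dtype=float)
        n = int(d["n_units"])
        minima = np.array(d["minima"], dtype=np.int64)
        tree, barriers = disconnectivity(energies, minima, n)
        return cls(
            energies=energies,
            minima=minima,
            basin_label=np.array(d["basin_label"], dtype=np.int64),
            basin_size=np.array(d["basin_size"], dtype=float),
            barriers=barriers,
            tree=tree,
        )


def build_landscape(energies: np.ndarray, n_units: int) -> Landscape:
    """Derive the complete landscape from a 2^N energy table."""
    energies = _check_energies(energies, n_units)
    minima = find_minima(energies, n_units)
    if len(minima) == 0:
        raise ValueError(
            "landscape has no strict local minimum (all-flat energies?)"
        )
    label = assign_basins(energies, minima, n_units)
    sizes = basin_sizes(label, minima)
    tree, barriers = disconnectivity(energies, minima, n_units)
    return Landscape(
        energies=energies,
        minima=minima,
        basin_label=label,
        basin_size=sizes,
        barriers=barriers,
        tree=tree,
    )


def landscape_from_params(params: MEMParams) -> Landscape:
    """Landscape of a fitted pairwise maximum-entropy model."""
    return build_landscape(pattern_energies(params), params.n_units)
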