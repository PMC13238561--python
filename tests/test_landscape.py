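import io as std_io

import numpy as np
import pytest
from Bio import Phylo

from eplsa import (
    MEMParams,
    assign_basins,
    basin_sizes,
    build_landscape,
    disconnectivity,
    find_minima,
    landscape_from_params,
    pattern_energies,
)
from helpers import (
    bottleneck_barrier,
    brute_descent_labels,
    brute_minima,
    random_landscape,
)


class TestFindMinima:
    def test_flat_landscape_has_none(self):
        assert len(find_minima(np.zeros(16), 4)) == 0

    def test_single_global_minimum_by_construction(self):
        center = 5
        energies = np.array(
            [bin(c ^ center).count("1") for c in range(16)], dtype=float
        )
        np.testing.assert_array_equal(find_minima(energies, 4), [center])

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            e = random_landscape(4, rng)
            np.testing.assert_array_equal(find_minima(e, 4), brute_minima(e, 4))

    def test_sorted_by_energy(self, rng):
        e = random_landscape(5, rng)
        minima = find_minima(e, 5)
        assert np.all(np.diff(e[minima]) >= 0)


class TestBasins:
    def test_minima_are_fixed_points(self, rng):
        e = random_landscape(4, rng)
        minima = find_minima(e, 4)
        label = assign_basins(e, minima, 4)
        np.testing.assert_array_equal(label[minima], minima)

    def test_single_minimum_owns_everything(self):
        center = 3
        e = np.array([bin(c ^ center).count("1") for c in range(32)], dtype=float)
        minima = find_minima(e, 5)
        label = assign_basins(e, minima, 5)
        assert set(label) == {center}
        np.testing.assert_allclose(basin_sizes(label, minima), [1.0])

    def test_matches_exhaustive_walk(self, rng):
        for _ in range(20):
            e = random_landscape(4, rng)
            minima = find_minima(e, 4)
            label = assign_basins(e, minima, 4)
            np.testing.assert_array_equal(label, brute_descent_labels(e, 4))

    def test_sizes_partition_unity(self, rng):
        e = random_landscape(6, rng)
        minima = find_minima(e, 6)
        sizes = basin_sizes(assign_basins(e, minima, 6), minima)
        assert sizes.sum() == pytest.approx(1.0)

    def test_symmetric_double_well(self):
        # h = 0 with uniform positive coupling: all-up / all-down minima,
        # equal basins by global spin-flip symmetry
        n = 5
        j = np.full((n, n), 0.4)
        np.fill_diagonal(j, 0.0)
        ls = landscape_from_params(MEMParams(h=np.zeros(n), J=j))
        assert set(ls.minima) == {0, 2**n - 1}
        np.testing.assert_allclose(ls.basin_size, [0.5, 0.5])

    def test_descent_monotone(self, rng):
        e = random_landscape(5, rng)
        minima = find_minima(e, 5)
        label = assign_basins(e, minima, 5)
        # every non-minimum has a strictly lower neighbor on its descent path
        for c in range(32):
            assert e[label[c]] <= e[c]


class TestDisconnectivity:
    def test_single_minimum(self):
        center = 0
        e = np.array([bin(c).count("1") for c in range(8)], dtype=float)
        minima = find_minima(e, 3)
        tree, barriers = disconnectivity(e, minima, 3)
        assert barriers.shape == (1, 1)
        assert barriers[0, 0] == e[center]
        assert tree.root.is_leaf and tree.root.code == center

    def test_two_minima_hand_saddle(self):
        # N=2 square: 00 and 11 are minima; the two 2-step paths cross
        # saddles of energy 1.0 (code 1) and 2.0 (code 2) -> barrier 1.0
        e = np.array([0.0, 1.0, 2.0, 0.1])
        minima = find_minima(e, 2)
        _, barriers = disconnectivity(e, minima, 2)
        assert set(minima) == {0, 3}
        assert barriers[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_bottleneck_oracle(self, n, rng):
        for _ in range(12):
            e = random_landscape(n, rng)
            minima = find_minima(e, n)
            if len(minima) < 2:
                continue
            _, barriers = disconnectivity(e, minima, n)
            for a in range(len(minima)):
                for b in range(a + 1, len(minima)):
                    oracle = bottleneck_barrier(e, n, minima[a], minima[b])
                    assert barriers[a, b] == pytest.approx(oracle, abs=0.0)

    def test_ultrametric_inequality(self, rng):
        for _ in range(10):
            e = random_landscape(5, rng)
            minima = find_minima(e, 5)
            if len(minima) < 3:
                continue
            _, b = disconnectivity(e, minima, 5)
            m = len(minima)
            for i in range(m):
                for j in range(m):
                    for k in range(m):
                        if len({i, j, k}) == 3:
                            assert b[i, j] <= max(b[i, k], b[k, j]) + 1e-12

    def test_barrier_dominates_endpoints(self, rng):
        e = random_landscape(5, rng)
        minima = find_minima(e, 5)
        _, b = disconnectivity(e, minima, 5)
        for i in range(len(minima)):
            for j in range(len(minima)):
                assert b[i, j] >= max(e[minima[i]], e[minima[j]]) - 1e-12


class TestTreeExport:
    def test_newick_structure_and_heights(self, rng):
        e = random_landscape(4, rng)
        ls = build_landscape(e, 4)
        newick = ls.tree.to_newick()
        tree = Phylo.read(std_io.StringIO(newick), "newick")
        leaves = tree.get_terminals()
        assert len(leaves) == ls.n_states
        names = {int(leaf.name.split("_")[0]) for leaf in leaves}
        assert names == set(ls.minima.tolist())
        if ls.n_states > 1:
            # root-to-leaf depth recovers (max barrier) - (leaf energy)
            root_height = ls.barriers.max()
            for leaf in leaves:
                code = int(leaf.name.split("_")[0])
                depth = tree.distance(tree.root, leaf)
                assert depth == pytest.approx(root_height - e[code], abs=1e-8)

    def test_merge_heights_equal_barriers(self, rng):
        e = random_landscape(4, rng)
        ls = build_landscape(e, 4)
        if ls.n_states < 2:
            pytest.skip("needs >= 2 minima")
        newick = ls.tree.to_newick()
        tree = Phylo.read(std_io.StringIO(newick), "newick")
        idx = {int(l.name.split("_")[0]): l for l in tree.get_terminals()}
        root_height = ls.barriers.max()
        for a in range(ls.n_states):
            for b in range(a + 1, ls.n_states):
                la, lb = idx[ls.minima[a]], idx[ls.minima[b]]
                mrca = tree.common_ancestor([la, lb])
                merge = root_height - tree.distance(tree.root, mrca)
                assert merge == pytest.approx(ls.barriers[a, b], abs=1e-8)


class TestLandscapeBundle:
    def test_from_mem_params_round_trip_dict(self, small_params):
        ls = landscape_from_params(small_params)
        d = ls.to_dict()
        from eplsa.landscape import Landscape

        back = Landscape.from_dict(d)
        np.testing.assert_array_equal(back.minima, ls.minima)
        np.testing.assert_allclose(back.barriers, ls.barriers)

    def test_energy_table_source(self, small_params):
        ls = landscape_from_params(small_params)
        np.testing.assert_allclose(ls.energies, pattern_energies(small_params))
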