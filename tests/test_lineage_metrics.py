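import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embgan.lineage_metrics import (
    LineageTree,
    branch_distance,
    compare_variability,
    cycle_vector,
    global_clock_ratio,
    pairwise_branch_distances,
)


def tree_from_durations(durations: dict[str, float], extra_leaf_time=5.0) -> LineageTree:
    """Build a tree in which each named cell completes a cycle of the given
    duration; birth times follow the parent chain ('AB' is the founder)."""
    tree = LineageTree()

    def birth_of(name):
        if name == "AB":
            return 0.0
        parent = name[:-1]
        return birth_of(parent) + durations[parent]

    for name in sorted(durations, key=len):
        b = birth_of(name)
        tree.add_cell(name, b, b + durations[name], None if name == "AB" else name[:-1])
    # give every divided cell two daughters so its cycle counts as complete
    for name in list(durations):
        b = birth_of(name) + durations[name]
        for suffix in "ap":
            if name + suffix not in tree:
                tree.add_cell(name + suffix, b, b + extra_leaf_time, name)
    return tree


class TestCycleVector:
    def test_given_order(self):
        tree = tree_from_durations({"AB": 10.0, "ABa": 12.0, "ABp": 9.0})
        assert np.array_equal(cycle_vector(tree, ["ABa", "ABp"]), [12.0, 9.0])
        assert np.array_equal(cycle_vector(tree, ["ABp", "ABa"]), [9.0, 12.0])

    def test_unknown_cell_raises_with_names(self):
        tree = tree_from_durations({"AB": 10.0})
        with pytest.raises(KeyError, match="ABx"):
            cycle_vector(tree, ["AB", "ABx"])

    def test_incomplete_cycle_raises(self):
        tree = tree_from_durations({"AB": 10.0})
        with pytest.raises(KeyError):
            cycle_vector(tree, ["ABa"])  # leaf: never divides


class TestBranchDistance:
    def test_identical_trees_zero(self):
        tree = tree_from_durations({"AB": 10.0, "ABa": 12.0, "ABp": 9.0})
        res = branch_distance(tree, tree)
        assert res.value == 0.0
        assert res.n_matched_cells == 3

    def test_hand_computed_example(self):
        # durations a:10 vs 13 and b:12 vs 16 -> sqrt(3^2 + 4^2) = 5
        ta = tree_from_durations({"AB": 50.0, "ABa": 10.0, "ABp": 12.0})
        tb = tree_from_durations({"AB": 50.0, "ABa": 13.0, "ABp": 16.0})
        res = branch_distance(ta, tb, restrict_to_lineage="ABa")
        assert res.value == pytest.approx(3.0)
        full = branch_distance(ta, tb)
        assert full.value == pytest.approx(5.0)
        assert full.cell_names == ["AB", "ABa", "ABp"]

    def test_empty_intersection_is_error_not_zero(self):
        ta = tree_from_durations({"AB": 10.0})
        tb = tree_from_durations({"AB": 10.0})
        with pytest.raises(ValueError):
            branch_distance(ta, tb, restrict_to_lineage="ABpp")

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_pseudometric_axioms_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        names = ["AB", "ABa", "ABp", "ABaa", "ABap"]
        trees = [
            tree_from_durations({n: float(rng.uniform(5, 30)) for n in names})
            for _ in range(3)
        ]
        d01 = branch_distance(trees[0], trees[1]).value
        d10 = branch_distance(trees[1], trees[0]).value
        d12 = branch_distance(trees[1], trees[2]).value
        d02 = branch_distance(trees[0], trees[2]).value
        assert d01 == d10  # symmetry
        assert d01 >= 0
        assert d02 <= d01 + d12 + 1e-9  # triangle inequality on shared cells


class TestGlobalClockRatio:
    def test_identical_trees_ratio_one(self):
        tree = tree_from_durations({"AB": 10.0, "ABa": 12.0, "ABp": 9.0})
        assert global_clock_ratio(tree, tree) == pytest.approx(1.0)

    def test_exact_scaling_recovered(self):
        base = {"AB": 10.0, "ABa": 12.0, "ABp": 9.0, "ABaa": 14.0}
        ta = tree_from_durations(base)
        tb = tree_from_durations({k: 1.10 * v for k, v in base.items()})
        assert global_clock_ratio(ta, tb) == pytest.approx(1.10, rel=1e-9)

    def test_reciprocality(self):
        rng = np.random.default_rng(8)
        names = ["AB", "ABa", "ABp", "ABaa", "ABap", "ABpa"]
        ta = tree_from_durations({n: float(rng.uniform(8, 25)) for n in names})
        tb = tree_from_durations({n: float(rng.uniform(8, 25)) for n in names})
        assert global_clock_ratio(ta, tb) * global_clock_ratio(tb, ta) == pytest.approx(
            1.0, rel=1e-9
        )

    def test_noisy_scaling_recovered_within_band(self):
        """n=50 cells, true 1.10x clock, small multiplicative noise."""
        rng = np.random.default_rng(12)
        names = ["AB"]
        for _ in range(49):
            names.append(names[rng.integers(0, len(names))] + rng.choice(["a", "p"]))
        names = sorted(set(names), key=len)
        base = {n: float(rng.uniform(10, 40)) for n in names}
        ta = tree_from_durations(base)
        tb = tree_from_durations(
            {k: 1.10 * v * float(rng.normal(1.0, 0.02)) for k, v in base.items()}
        )
        assert 1.05 <= global_clock_ratio(ta, tb) <= 1.15

    def test_degenerate_scatter_raises(self):
        tree = tree_from_durations({"AB": 10.0, "ABa": 10.0, "ABp": 10.0})
        with pytest.raises(ValueError):
            global_clock_ratio(tree, tree)


def _noisy_group(rng, base, cv, n_trees):
    return [
        tree_from_durations(
            {k: float(v * rng.lognormal(0, cv)) for k, v in base.items()}
        )
        for _ in range(n_trees)
    ]


class TestCompareVariability:
    BASE = {"AB": 20.0, "ABa": 18.0, "ABp": 22.0, "ABaa": 25.0, "ABpp": 24.0}

    def test_identical_groups_equal_medians_p_one(self):
        rng = np.random.default_rng(0)
        group = _noisy_group(rng, self.BASE, 0.1, 4)
        table = compare_variability(group, list(group))
        row = table.iloc[0]
        assert row.median_a == row.median_b
        assert row.p_value == pytest.approx(1.0)

    def test_clones_have_zero_median(self):
        rng = np.random.default_rng(1)
        clones = [tree_from_durations(self.BASE) for _ in range(3)]
        hetero = _noisy_group(rng, self.BASE, 0.2, 3)
        table = compare_variability(clones, hetero)
        row = table.iloc[0]
        assert row.median_a == 0.0
        assert row.median_b > 0.0

    def test_double_noise_doubles_median_at_large_n(self):
        """Pairwise L2 of iid lognormal duration noise scales ~linearly with
        sigma, so 2x CV gives ~2x median branch distance."""
        rng = np.random.default_rng(2)
        a = _noisy_group(rng, self.BASE, 0.20, 12)
        b = _noisy_group(rng, self.BASE, 0.10, 12)
        table = compare_variability(a, b)
        row = table.iloc[0]
        assert 1.5 <= row.median_a / row.median_b <= 2.6

    def test_lineage_restriction_column(self):
        rng = np.random.default_rng(3)
        a = _noisy_group(rng, self.BASE, 0.2, 3)
        b = _noisy_group(rng, self.BASE, 0.1, 3)
        table = compare_variability(a, b, lineages=["ABa", "ABp"])
        assert list(table.lineage) == ["ABa", "ABp"]

    def test_single_tree_group_raises(self):
        rng = np.random.default_rng(4)
        group = _noisy_group(rng, self.BASE, 0.1, 2)
        with pytest.raises(ValueError):
            compare_variability(group[:1], group)

    def test_pairwise_count(self):
        rng = np.random.default_rng(5)
        group = _noisy_group(rng, self.BASE, 0.1, 5)
        assert pairwise_branch_distances(group).size == 10
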