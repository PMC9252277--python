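"""Index and L-shaped selection, frontiers, and their optimality guarantees."""

import itertools

import numpy as np
import pytest

from mtgs import (
    CapacityError,
    GeneticValues,
    WeightVector,
    index_select,
    lshaped_objective,
    lshaped_select,
    lshaped_weight_regions_2traits,
    pareto_front,
    supported_front,
    weights_for_solution,
)
from conftest import random_instance


def enumerate_best_sum(values, w, S):
    """Oracle: best weighted-sum subset by full enumeration."""
    n = values.shape[0]
    best, best_obj = None, -np.inf
    for combo in itertools.combinations(range(n), S):
        obj = float(w @ values[list(combo)].sum(axis=0))
        if obj > best_obj + 1e-12:
            best, best_obj = combo, obj
    return best, best_obj


def enumerate_best_maxmin(values, w, S):
    """Oracle: best max-min subset by full enumeration."""
    n = values.shape[0]
    best, best_obj = None, -np.inf
    for combo in itertools.combinations(range(n), S):
        obj = float((values[list(combo)].sum(axis=0) / w).min())
        if obj > best_obj + 1e-12:
            best, best_obj = combo, obj
    return best, best_obj


def dominance_oracle(points):
    """All-pairs O(n^2) non-dominated filter."""
    pts = np.asarray(points, float)
    keep = []
    for i, p in enumerate(pts):
        if not any((q >= p).all() and (q > p).any() for j, q in enumerate(pts)):
            keep.append(i)
    return keep


class TestIndexSelect:
    @pytest.mark.parametrize(
        "w, expected",
        [((0.1, 0.9), ("i1", "i2")), ((0.5, 0.5), ("i3", "i4"))],
    )
    def test_worked_example_pairs(self, example1, w, expected):
        res = index_select(example1.values, w, 2)
        assert res.individual_ids == expected
        # agrees with enumeration over all 6 pairs
        combo, obj = enumerate_best_sum(example1.values.values, np.array(w), 2)
        assert res.selected == combo
        assert res.objective == pytest.approx(obj)

    def test_single_trait_is_truncation_selection(self, rng):
        vals = rng.normal(size=(9, 1))
        V = GeneticValues([f"i{i}" for i in range(9)], ["t"], vals)
        res = index_select(V, [3.0], 4)
        top = set(np.argsort(-vals[:, 0])[:4])
        assert set(res.selected) == top

    def test_oversized_selection_raises(self, example1):
        with pytest.raises(ValueError):
            index_select(example1.values, [1, 1], 5)

    def test_score_ties_break_by_identifier(self):
        V = GeneticValues(["b", "a", "c"], ["t"], [[1.0], [1.0], [0.0]])
        res = index_select(V, [1.0], 1)
        assert res.individual_ids == ("a",)

    def test_weight_rescaling_does_not_change_selection(self, rng):
        for _ in range(20):
            Vn, w, S = random_instance(rng)
            V = GeneticValues(Vn.individual_ids, Vn.trait_ids, Vn.values)
            c = float(rng.uniform(0.1, 10))
            assert index_select(V, w, S).selected == index_select(V, c * w, S).selected


class TestLshapedObjective:
    def test_worked_example_cross_c3(self, example1_normalized):
        # i1 + i4 sums: (0.49, 0.39); equal weights -> 0.78
        obj = lshaped_objective((0, 3), example1_normalized, [0.5, 0.5])
        assert obj == pytest.approx(0.78)

    def test_symmetric_case(self):
        Vn = GeneticValues(["a", "b"], ["t1", "t2"], [[0.3, 0.3], [0.1, 0.1]],
                           is_normalized=True)
        assert lshaped_objective((0, 1), Vn, [0.5, 0.5]) == pytest.approx(0.8)

    def test_inverse_homogeneity_in_weights(self, rng):
        Vn, w, S = random_instance(rng)
        sel = tuple(range(S))
        c = 3.7
        assert lshaped_objective(sel, Vn, c * w) == pytest.approx(
            lshaped_objective(sel, Vn, w) / c
        )


class TestLshapedSelect:
    def test_equal_weights_pick_unsupported_cross(self, example1_normalized):
        res = lshaped_select(example1_normalized, [0.5, 0.5], 2)
        assert res.individual_ids == ("i1", "i4")
        assert res.objective == pytest.approx(0.78)

    def test_constructive_weights_recover_cross_c2(self, example1_normalized):
        res = lshaped_select(example1_normalized, [0.35, 0.48], 2)
        assert res.individual_ids == ("i1", "i3")
        assert res.objective == pytest.approx(1.0)

    def test_single_trait_reduces_to_index_selection(self, rng):
        vals = rng.uniform(0.1, 0.9, size=(8, 1))
        Vn = GeneticValues([f"i{i}" for i in range(8)], ["t"], vals, True)
        V = GeneticValues(Vn.individual_ids, Vn.trait_ids, vals)
        assert (lshaped_select(Vn, [1.0], 3).selected
                == index_select(V, [1.0], 3).selected)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            Vn, w, S = random_instance(rng)
            res = lshaped_select(Vn, w, S)
            _, best = enumerate_best_maxmin(Vn.values, w, S)
            assert res.objective == pytest.approx(best)

    def test_milp_backend_agrees_with_enumeration(self, rng):
        for _ in range(10):
            Vn, w, S = random_instance(rng, n_max=8)
            a = lshaped_select(Vn, w, S, backend="enumerate")
            b = lshaped_select(Vn, w, S, backend="milp")
            assert b.objective == pytest.approx(a.objective)

    def test_enumeration_cap_raises_capacity_error(self, rng):
        vals = rng.uniform(0.1, 0.9, size=(30, 2))
        Vn = GeneticValues([f"i{i}" for i in range(30)], ["a", "b"], vals, True)
        with pytest.raises(CapacityError):
            lshaped_select(Vn, [1, 1], 2, backend="enumerate", max_enumerate=10)

    def test_weight_rescaling_does_not_change_selection(self, rng):
        for _ in range(20):
            Vn, w, S = random_instance(rng)
            c = float(rng.uniform(0.1, 10))
            assert (lshaped_select(Vn, w, S).selected
                    == lshaped_select(Vn, c * w, S).selected)


class TestConstructiveWeights:
    @pytest.mark.parametrize(
        "pair, expected",
        [((0, 2), (0.35, 0.48)), ((2, 3), (0.74, 0.21))],  # crosses c2, c6
    )
    def test_worked_example_trait_sums(self, example1_normalized, pair, expected):
        w = weights_for_solution(pair, example1_normalized)
        assert w.values == pytest.approx(expected)

    def test_pareto_subsets_recover_as_optima(self, rng):
        """Every Pareto-optimal subset attains the max-min optimum (value 1)
        under its own constructive weights."""
        for _ in range(20):
            Vn, _, S = random_instance(rng, n_max=8, S_max=2)
            combos = list(itertools.combinations(range(Vn.n_individuals), S))
            sums = np.array([Vn.values[list(c)].sum(axis=0) for c in combos])
            for ci in dominance_oracle(sums):
                w = weights_for_solution(combos[ci], Vn)
                res = lshaped_select(Vn, w, S)
                assert res.objective == pytest.approx(1.0)


class TestFrontiers:
    def test_worked_example_crosses_all_pareto(self, example1):
        front = pareto_front(example1.cross_sums)
        assert [example1.cross_names[i] for i in front.indices] == example1.pareto_names

    def test_strict_dominance_filtered(self):
        front = pareto_front([(1.0, 1.0), (0.0, 0.0)])
        assert front.indices == [0]

    def test_duplicates_retained(self):
        front = pareto_front([(1.0, 0.0), (1.0, 0.0), (0.0, 1.0)])
        assert front.indices == [0, 1, 2]

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(30):
            n, K = int(rng.integers(3, 15)), int(rng.integers(2, 5))
            pts = np.round(rng.uniform(0, 1, size=(n, K)), 1)  # force ties
            assert pareto_front(pts).indices == dominance_oracle(pts)

    def test_worked_example_supported_is_three_crosses(self, example1):
        front = supported_front(example1.cross_sums)
        assert [example1.cross_names[i] for i in front.indices] == ["c1", "c5", "c6"]

    def test_dominating_point_is_sole_supported(self):
        assert supported_front([(0.2, 0.2), (0.6, 0.6)]).indices == [1]

    def test_supported_subset_of_pareto(self, rng):
        for _ in range(20):
            n, K = int(rng.integers(2, 12)), int(rng.integers(2, 4))
            pts = rng.uniform(0, 1, size=(n, K))
            sf = set(supported_front(pts).indices)
            pf = set(pareto_front(pts).indices)
            assert sf <= pf

    def test_hull_matches_dense_weight_sweep(self, rng):
        for _ in range(15):
            pts = rng.uniform(0, 1, size=(int(rng.integers(3, 12)), 2))
            found = set()
            for w1 in np.linspace(1e-4, 1 - 1e-4, 2001):
                scores = pts @ np.array([w1, 1 - w1])
                m = scores.max()
                winners = np.flatnonzero(scores >= m - 1e-12)
                if winners.size == 1:  # strict maximizer only
                    found.add(int(winners[0]))
            assert found == set(supported_front(pts).indices)

    def test_hull_and_lp_paths_agree(self, rng):
        for _ in range(15):
            pts = rng.uniform(0, 1, size=(int(rng.integers(3, 12)), 2))
            a = set(supported_front(pts, method="hull").indices)
            b = set(supported_front(pts, method="lp").indices)
            assert a == b

    def test_weakly_supported_point_included_only_with_flag(self):
        pts = [(0.0, 1.0), (0.5, 0.5), (1.0, 0.0)]  # middle lies on the segment
        assert supported_front(pts).indices == [0, 2]
        assert supported_front(pts, include_weak=True).indices == [0, 1, 2]


class TestWeightRegions:
    def test_every_cross_owns_an_interval(self, example1):
        regions = lshaped_weight_regions_2traits(example1.cross_sums)
        names = [example1.cross_names[idx] for _, idx, _ in regions]
        assert names == example1.pareto_names
        assert regions[0][0][0] == 0.0 and regions[-1][0][1] == 1.0
        # intervals are contiguous and increasing
        for (a, b), (c, d) in zip((r[0] for r in regions), (r[0] for r in regions[1:])):
            assert a < b == c < d

    def test_single_point_spans_unit_interval(self):
        ((lo, hi), idx, vec), = lshaped_weight_regions_2traits([(0.4, 0.6)])
        assert (lo, hi, idx) == (0.0, 1.0, 0)
        assert vec == pytest.approx([0.4, 0.6])

    def test_interval_midpoints_reproduce_their_point(self, example1, example1_normalized):
        """Self-consistency: solving the selection model at each interval's
        midpoint recovers exactly that interval's cross."""
        regions = lshaped_weight_regions_2traits(example1.cross_sums)
        for (lo, hi), idx, _ in regions:
            mid = (lo + hi) / 2
            res = lshaped_select(example1_normalized, [mid, 1 - mid], 2)
            assert set(res.individual_ids) == set(example1.cross_pairs[idx])

    def test_non_two_trait_input_rejected(self, rng):
        with pytest.raises(ValueError):
            lshaped_weight_regions_2traits(rng.uniform(0.1, 0.9, size=(4, 3)))


class TestOptimalityGuarantees:
    def test_index_optimum_is_never_dominated(self, rng):
        """Weighted-sum optima with strictly positive weights are Pareto
        optimal among all size-S subset trait-sum vectors."""
        for _ in range(200):
            Vn, w, S = random_instance(rng)
            V = GeneticValues(Vn.individual_ids, Vn.trait_ids, Vn.values)
            res = index_select(V, w, S)
            combos = list(itertools.combinations(range(V.n_individuals), S))
            sums = np.array([V.values[list(c)].sum(axis=0) for c in combos])
            mine = V.values[list(res.selected)].sum(axis=0)
            dominated = ((sums >= mine).all(axis=1) & (sums > mine).any(axis=1)).any()
            assert not dominated

    def test_every_pareto_subset_reachable_by_lshaped(self, rng):
        """Constructive weights make each Pareto-optimal subset an exact
        max-min optimum (objective 1)."""
        for _ in range(200):
            Vn, _, S = random_instance(rng, n_max=9, S_max=3)
            combos = list(itertools.combinations(range(Vn.n_individuals), S))
            sums = np.array([Vn.values[list(c)].sum(axis=0) for c in combos])
            pareto = dominance_oracle(sums)
            for ci in pareto[:4]:  # cap per instance to bound runtime
                w = weights_for_solution(combos[ci], Vn)
                assert lshaped_select(Vn, w, S).objective == pytest.approx(1.0)


class TestUnitsInvariance:
    def test_lshaped_invariant_index_not(self, rng):
        """L-shaped selection (with relative-epsilon normalization recomputed
        after rescaling) is invariant to per-trait affine unit changes; raw
        weighted-sum selection is not, and a concrete instance flips."""
        from mtgs import compute_bounds, normalize_values

        flipped = False
        for _ in range(100):
            n, K = int(rng.integers(4, 10)), 2
            vals = rng.normal(size=(n, K))
            a = rng.uniform(0.2, 5.0, size=K)
            b = rng.normal(size=K)
            ids = [f"i{i}" for i in range(n)]
            V1 = GeneticValues(ids, ["t1", "t2"], vals)
            V2 = GeneticValues(ids, ["t1", "t2"], vals * a + b)
            w = rng.uniform(0.2, 2.0, size=K)
            n1 = normalize_values(V1, compute_bounds(V1, 1e-6))
            n2 = normalize_values(V2, compute_bounds(V2, 1e-6))
            assert (lshaped_select(n1, w, 2).selected
                    == lshaped_select(n2, w, 2).selected)
            if index_select(V1, w, 2).selected != index_select(V2, w, 2).selected:
                flipped = True
        assert flipped, "expected at least one unit-change flip for index selection"


def test_weight_vector_rejects_nonpositive():
    with pytest.raises(ValueError):
        WeightVector(np.array([0.5, 0.0]))
    assert WeightVector.normalized([2, 2]).values == pytest.approx([0.5, 0.5])
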