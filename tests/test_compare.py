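"""Fold-change calls, Venn partitions and Spearman correlation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pirnatools import fold_change_and_call, intersect_sets, spearman
from pirnatools.compare import region
from pirnatools.errors import ParameterError
from pirnatools.quantify import CountMatrix, classify_and_count, merge_samples
from pirnatools.mapper import Alignment
from _oracles import spearman_by_definition


def matrix_from_cpm(cpm_a: dict, cpm_b: dict, denominator=1e6) -> CountMatrix:
    """Build a floored two-sample matrix whose piRNA '+' CPM equal the dicts."""
    features = sorted(set(cpm_a) | set(cpm_b))

    def alns(cpm):
        return [Alignment(f"r{f}", f, "+", 0, 25, 0, cpm.get(f, 0.0))
                for f in features]

    ma = classify_and_count(alns(cpm_a), "A", denominator, features=features)
    mb = classify_and_count(alns(cpm_b), "B", denominator, features=features)
    return merge_samples([ma, mb]).normalize_and_floor(floor_cpm=0.0)


class TestFoldChange:
    def test_boundary_fold_exactly_ten(self):
        m = matrix_from_cpm({"f": 999.0}, {"f": 99.0})
        rep = fold_change_and_call(m, "A", "B", threshold=10.0, epsilon=1.0)
        assert rep.table.loc["f", "fold"] == pytest.approx(10.0)
        assert rep.table.loc["f", "call"] == "higher_in_a"

    def test_equal_cpm_no_call(self):
        m = matrix_from_cpm({"f": 500.0}, {"f": 500.0})
        rep = fold_change_and_call(m, "A", "B")
        assert rep.table.loc["f", "fold"] == 1.0
        assert rep.table.loc["f", "call"] == "none"

    def test_absent_in_both_skipped(self):
        m = matrix_from_cpm({"f": 100.0, "g": 10.0}, {"f": 100.0, "g": 10.0},
                            denominator=1e6)
        floored = CountMatrix(m.raw, m.denominators).normalize_and_floor(25.0)
        rep = fold_change_and_call(floored, "A", "B")
        assert "g" not in rep.table.index  # under the floor in both samples
        assert "f" in rep.table.index

    def test_absent_in_one_treated_as_zero(self):
        m = matrix_from_cpm({"f": 400.0, "g": 300.0}, {"f": 400.0})
        floored = CountMatrix(m.raw, m.denominators).normalize_and_floor(25.0)
        rep = fold_change_and_call(floored, "A", "B", epsilon=1.0)
        assert rep.table.loc["g", "fold"] == pytest.approx(301.0)
        assert rep.table.loc["g", "call"] == "higher_in_a"

    def test_unknown_sample_rejected(self):
        m = matrix_from_cpm({"f": 1.0}, {"f": 1.0})
        with pytest.raises(KeyError):
            fold_change_and_call(m, "A", "nope")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        cpm_a = {f"f{i}": float(rng.integers(0, 2000)) for i in range(12)}
        cpm_b = {f"f{i}": float(rng.integers(0, 2000)) for i in range(12)}
        m = matrix_from_cpm(cpm_a, cpm_b)
        fwd = fold_change_and_call(m, "A", "B")
        rev = fold_change_and_call(m, "B", "A")
        assert np.allclose(fwd.table["fold"], 1.0 / rev.table["fold"])
        assert fwd.higher_in_a == rev.higher_in_b
        assert fwd.higher_in_b == rev.higher_in_a

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        cpm_a = {f"f{i}": float(rng.integers(0, 3000)) for i in range(40)}
        cpm_b = {f"f{i}": float(rng.integers(0, 3000)) for i in range(40)}
        m = matrix_from_cpm(cpm_a, cpm_b)
        lo = fold_change_and_call(m, "A", "B", threshold=5.0)
        hi = fold_change_and_call(m, "A", "B", threshold=20.0)
        assert hi.higher_in_a <= lo.higher_in_a
        assert hi.higher_in_b <= lo.higher_in_b


class TestIntersectSets:
    def test_two_sets_shared_region(self):
        regions = intersect_sets({"X": {"A", "B", "C"}, "Y": {"B", "C", "D"}})
        shared = region(regions, "X", "Y")
        assert shared.members == ("B", "C") and shared.count == 2
        assert region(regions, "X").members == ("A",)
        assert region(regions, "Y").members == ("D",)

    def test_identical_sets_concentrate_in_full_intersection(self):
        s = {"a", "b", "c"}
        regions = intersect_sets({"X": s, "Y": s, "Z": s})
        assert region(regions, "X", "Y", "Z").count == 3
        assert sum(r.count for r in regions) == 3

    def test_region_count_and_partition(self):
        rng = np.random.default_rng(4)
        sets = {f"s{i}": set(rng.choice(30, size=12, replace=False).tolist())
                for i in range(3)}
        regions = intersect_sets(sets)
        assert len(regions) == 7  # 2^3 - 1
        union = set().union(*sets.values())
        assert sum(r.count for r in regions) == len(union)

    def test_single_set_rejected(self):
        with pytest.raises(ParameterError):
            intersect_sets({"X": {"a"}})


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        assert spearman([1, 2, 3, 10], [0.1, 5, 6, 7]).r == 1.0

    def test_reversed_ranks_is_minus_one(self):
        assert spearman([1, 2, 3, 4], [9, 7, 5, 1]).r == -1.0

    def test_ties_match_average_rank_definition(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.integers(0, 5, size=15).astype(float)
            y = rng.integers(0, 5, size=15).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            assert spearman(x, y).r == pytest.approx(spearman_by_definition(x, y),
                                                     rel=1e-12)

    def test_constant_vector_degenerate(self):
        res = spearman([1.0, 1.0, 1.0], [1, 2, 3])
        assert res.degenerate and math.isnan(res.r)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            spearman([1, 2, 3], [1, 2])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(20)
        y = rng.random(20)
        base = spearman(x, y).r
        assert spearman(np.exp(3 * x), y).r == pytest.approx(base, rel=1e-12)
        assert spearman(x, y**3 + 5).r == pytest.approx(base, rel=1e-12)
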