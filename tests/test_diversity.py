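from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import skbio
from microdyn import (PhylogeneticTree, ValidationError, inverse_simpson,
                      goods_coverage, rarefaction_curve, sorensen, bray_curtis,
                      unifrac, distance_matrix, within_subject_series,
                      between_subjects_series)
from microdyn.preprocess import NormalizedTable
from conftest import make_table


def _norm(values, subjects=None, days=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    subjects = subjects or [f"s{j}" for j in range(n)]
    days = days or list(range(1, n + 1))
    t = make_table(np.ones_like(values, dtype=int), subjects, days)
    # columns follow the table's (subject, day) sample ordering
    order = sorted(range(n), key=lambda j: (subjects[j], days[j]))
    return NormalizedTable([f"A{i}" for i in range(len(values))], t.samples,
                           values[:, order], "scaled")


class TestAlpha:
    @pytest.mark.parametrize("counts,expected", [
        ([10, 10, 10, 10], 4.0),
        ([7, 0, 0], 1.0),
        ([50, 30, 20], 1 / (0.25 + 0.09 + 0.04)),
    ])
    def test_inverse_simpson_values(self, counts, expected):
        assert inverse_simpson(counts) == pytest.approx(expected, abs=1e-4)

    def test_inverse_simpson_rejects_empty(self):
        with pytest.raises(ValidationError):
            inverse_simpson([0, 0])


class TestCoverage:
    def test_no_singletons_full_coverage(self):
        assert goods_coverage([5, 10, 3]) == 100.0

    def test_one_singleton_in_ten_thousand(self):
        assert goods_coverage([9999, 1]) == pytest.approx(99.99)

    def test_all_singletons_zero_coverage(self):
        assert goods_coverage([1, 1, 1, 1]) == 0.0

    def test_rejects_scaled_counts(self):
        with pytest.raises(ValidationError):
            goods_coverage([1.5, 2.0])


class TestRarefaction:
    def test_full_depth_gives_observed_richness(self):
        assert rarefaction_curve([5, 3, 2], [10])[0] == pytest.approx(3.0)

    def test_single_read_gives_one(self):
        assert rarefaction_curve([5, 3, 2], [1])[0] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        # expected richness over all C(10, 2) subsets of reads from [5, 3, 2]
        reads = [0] * 5 + [1] * 3 + [2] * 2
        expected = np.mean([len({reads[i], reads[j]})
                            for i, j in combinations(range(10), 2)])
        assert rarefaction_curve([5, 3, 2], [2])[0] == pytest.approx(expected)

    def test_depth_beyond_total_rejected(self):
        with pytest.raises(ValidationError):
            rarefaction_curve([2, 2], [5])


class TestSorensen:
    def test_identical_and_disjoint(self):
        assert sorensen([1, 1, 0], [2, 5, 0])[0] == 0.0
        assert sorensen([1, 0, 0], [0, 2, 3])[0] == 1.0

    def test_worked_example(self):
        # A=3, B=4, J=2 -> (3+4-4)/(3+4)
        d, dec = sorensen([1, 1, 1, 0, 0, 0], [1, 1, 0, 1, 1, 0])
        assert d == pytest.approx(3 / 7)
        assert (dec.A, dec.B, dec.C, dec.J) == (2.0, 1.0, 2.0, 2)

    def test_presence_decomposition_has_a_equal_j(self, rng):
        x, y = rng.integers(0, 3, 12), rng.integers(0, 3, 12)
        x[0] = 1
        _, dec = sorensen(x, y)
        assert dec.A == dec.J

    def test_both_empty_rejected(self):
        with pytest.raises(ValidationError):
            sorensen([0, 0], [0, 0])


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        assert bray_curtis([1, 2], [1, 2])[0] == 0.0
        assert bray_curtis([1, 0], [0, 3])[0] == 1.0

    def test_worked_example_and_decomposition(self):
        d, dec = bray_curtis([1, 2, 0], [0, 2, 3])
        assert d == pytest.approx(0.5)
        assert (dec.A, dec.B, dec.C) == (2.0, 1.0, 3.0)
        assert (dec.B + dec.C) / (2 * dec.A + dec.B + dec.C) == pytest.approx(d)

    def test_two_formula_identity_on_random_pairs(self, rng):
        for _ in range(200):
            x = rng.random(30) * rng.integers(0, 2, 30)
            y = rng.random(30) * rng.integers(0, 2, 30)
            x[0] += 0.5
            d, dec = bray_curtis(x, y)
            alt = (dec.B + dec.C) / (2 * dec.A + dec.B + dec.C)
            assert abs(d - alt) < 1e-12

    def test_negative_entries_rejected(self):
        with pytest.raises(ValidationError):
            bray_curtis([1, -1], [1, 1])


@pytest.fixture
def three_leaf_tree():
    return PhylogeneticTree(skbio.TreeNode.read(["((A:1,B:1):1,C:2);"]))


class TestUnifrac:
    def test_identical_samples_zero_both_variants(self, three_leaf_tree):
        for w in (False, True):
            assert unifrac([1, 2, 3], [1, 2, 3], ["A", "B", "C"],
                           three_leaf_tree, weighted=w) == pytest.approx(0.0)

    def test_disjoint_subtrees_meet_at_root(self):
        tree = PhylogeneticTree(skbio.TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1);"]))
        d = unifrac([1, 1, 0, 0], [0, 0, 1, 1], list("ABCD"), tree)
        assert d == pytest.approx(1.0)

    def test_edge_by_edge_example(self, three_leaf_tree):
        # {A} vs {B}: unique length 2 of spanned 3
        d = unifrac([1, 0, 0], [0, 1, 0], ["A", "B", "C"], three_leaf_tree)
        assert d == pytest.approx(2 / 3)

    def test_missing_leaf_named_in_error(self, three_leaf_tree):
        with pytest.raises(ValidationError, match="X"):
            unifrac([1, 0, 0, 1], [0, 1, 0, 0], ["A", "B", "C", "X"],
                    three_leaf_tree)

    def test_star_tree_unweighted_is_jaccard_hence_sorensen_transform(self, rng):
        # classical identity: on a unit-branch star tree, unweighted UniFrac
        # reduces to the Jaccard distance (unique / union branch length),
        # which maps onto Sorensen through d_s = d_j / (2 - d_j)
        n = 10
        names = [f"L{i}" for i in range(n)]
        # star metric written as a rooted binary tree via zero-length
        # internal edges (skbio requires a rooted topology)
        half1 = ",".join(f"{x}:1" for x in names[:5])
        half2 = ",".join(f"{x}:1" for x in names[5:])
        star = PhylogeneticTree(skbio.TreeNode.read(
            [f"(({half1}):0,({half2}):0);"]))
        for _ in range(10):
            x = rng.integers(0, 2, n)
            y = rng.integers(0, 2, n)
            if not (x.any() and y.any()):
                continue
            px, py = x > 0, y > 0
            jaccard = 1.0 - (px & py).sum() / (px | py).sum()
            d = unifrac(x, y, names, star)
            assert d == pytest.approx(jaccard)
            assert d / (2 - d) == pytest.approx(sorensen(x, y)[0])


class TestDistanceMatrix:
    def test_duplicate_sample_has_zero_distance(self):
        norm = _norm([[1, 1, 3], [2, 2, 0], [5, 5, 1]])
        d = distance_matrix(norm, "bray_curtis")
        assert d[("s0_d1", "s1_d2")] == pytest.approx(0.0)

    def test_matches_element_ops(self, rng):
        values = rng.random((15, 5)) * rng.integers(0, 2, size=(15, 5))
        values[0] += 0.2
        norm = _norm(values)
        dm_b = distance_matrix(norm, "bray_curtis")
        dm_s = distance_matrix(norm, "sorensen")
        for i, j in combinations(range(5), 2):
            li, lj = norm.sample_ids[i], norm.sample_ids[j]
            assert dm_b[(li, lj)] == pytest.approx(
                bray_curtis(values[:, i], values[:, j])[0])
            assert dm_s[(li, lj)] == pytest.approx(
                sorensen(values[:, i], values[:, j])[0])

    def test_metric_axioms_on_random_tables(self, rng):
        values = rng.random((25, 8)) * rng.integers(0, 2, size=(25, 8))
        values[0] += 0.2
        for index in ("bray_curtis", "sorensen"):
            d = distance_matrix(_norm(values), index)
            assert np.allclose(np.diag(d.values), 0)
            assert np.allclose(d.values, d.values.T)
            assert (d.values >= -1e-12).all() and (d.values <= 1 + 1e-12).all()

    def test_unifrac_matrix_matches_element_op(self, rng, three_leaf_tree):
        values = rng.integers(1, 9, size=(3, 4)).astype(float)
        norm = _norm(values)
        norm.asv_ids = ["A", "B", "C"]
        dm = distance_matrix(norm, "unweighted_unifrac", three_leaf_tree)
        li, lj = norm.sample_ids[0], norm.sample_ids[2]
        assert dm[(li, lj)] == pytest.approx(
            unifrac(values[:, 0], values[:, 2], ["A", "B", "C"], three_leaf_tree))


class TestSeries:
    def test_within_identical_communities_all_zero(self):
        norm = _norm([[3, 3, 3, 3], [1, 1, 1, 1]],
                     subjects=["a", "a", "b", "b"], days=[1, 9, 1, 9])
        s = within_subject_series(norm)
        assert s.values == pytest.approx([0.0, 0.0])

    def test_within_point_count_and_day_assignment(self):
        norm = _norm(np.arange(12).reshape(2, 6) + 1.0,
                     subjects=["a", "a", "a", "b", "b", "b"],
                     days=[1, 9, 30, 1, 9, 30])
        s = within_subject_series(norm)
        assert len(s.points) == 4
        assert sorted(s.days) == [9, 9, 30, 30]  # later-day assignment

    def test_single_timepoint_subject_excluded(self):
        norm = _norm([[1, 2, 3]], subjects=["a", "a", "b"], days=[1, 9, 1])
        s = within_subject_series(norm)
        assert set(s.subjects) == {"a"}

    def test_between_mean_of_pairwise(self):
        # three subjects at one day: mean of the three pairwise distances
        values = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, 0.5]])
        norm = _norm(values, subjects=["a", "b", "c"], days=[5, 5, 5])
        expected = np.mean([bray_curtis(values[:, i], values[:, j])[0]
                            for i, j in combinations(range(3), 2)])
        s = between_subjects_series(norm)
        assert s.values == pytest.approx([expected])

    def test_between_skips_single_subject_days(self):
        norm = _norm([[1, 2, 3], [2, 1, 1]],
                     subjects=["a", "b", "a"], days=[1, 1, 9])
        s = between_subjects_series(norm)
        assert list(s.days) == [1]


@settings(max_examples=30, deadline=None)
@given(st.lists(st.integers(0, 50), min_size=3, max_size=20),
       st.lists(st.integers(0, 50), min_size=3, max_size=20))
def test_indexes_bounded_and_symmetric(xs, ys):
    n = min(len(xs), len(ys))
    x, y = np.array(xs[:n]), np.array(ys[:n])
    if x.sum() == 0 or y.sum() == 0:
        return
    for fn in (bray_curtis, sorensen):
        d_xy, _ = fn(x, y)
        d_yx, _ = fn(y, x)
        assert 0 <= d_xy <= 1
        assert d_xy == pytest.approx(d_yx)
        assert fn(x, x)[0] == pytest.approx(0.0)
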