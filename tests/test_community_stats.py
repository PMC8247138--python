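import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from microdyn import (DistanceMatrix, ValidationError, nmds, permanova,
                      betadisper, anova_oneway, bh_adjust)


def _dm(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"s{i}" for i in range(values.shape[0])]
    return DistanceMatrix(labels, values, "bray_curtis")


def _euclid_dm(points):
    return _dm(squareform(pdist(np.asarray(points, dtype=float))))


# ---------------------------------------------------------------------------
# Reference values computed with vegan 2.7 (adonis2 sequential/by-terms and
# betadisper with spatial medians) on the 12-sample Bray-Curtis fixture
# below; frozen to the printed precision.
# ---------------------------------------------------------------------------
VEGAN_COMMUNITY = np.array([
    [27, 9, 31, 12, 8, 31, 25, 27], [39, 15, 33, 13, 22, 23, 8, 7],
    [9, 26, 24, 37, 28, 9, 36, 37], [29, 26, 5, 0, 10, 17, 0, 35],
    [18, 27, 8, 13, 0, 29, 30, 8], [28, 0, 15, 6, 29, 13, 18, 18],
    [19, 10, 22, 32, 19, 7, 0, 5], [0, 0, 0, 23, 32, 34, 26, 24],
    [13, 37, 25, 28, 29, 34, 28, 37], [21, 21, 10, 37, 22, 19, 12, 10],
    [25, 18, 22, 26, 35, 13, 27, 36], [18, 10, 11, 13, 25, 10, 33, 14],
])
VEGAN_META = pd.DataFrame({
    "subject": list("AAABBBCCCDDD"),
    "diet": ["FV", "TV", "NR"] * 4,
    "day": [1, 5, 9, 2, 6, 12, 3, 8, 11, 4, 7, 10],
})
VEGAN_SS = {"subject": 0.1474597037, "diet": 0.1006617498, "day": 0.0595465607}
VEGAN_R2 = {"subject": 0.2118681754, "diet": 0.1446294868, "day": 0.0855557203}
VEGAN_F = {"subject": 0.63288, "diet": 0.64804, "day": 0.76670}
VEGAN_RESID_SS = 0.3883294068
VEGAN_DISPER_DISTANCES = [0.2575533, 0.2563237, 0.1310881, 0.3037620,
                          0.2637240, 0.2587223, 0.2310472, 0.2940171,
                          0.1547380, 0.1421030, 0.1134586, 0.1672503]
VEGAN_DISPER_F = 0.8436711
VEGAN_DISPER_P = 0.4615062


@pytest.fixture(scope="module")
def vegan_dm():
    return _dm(squareform(pdist(VEGAN_COMMUNITY, "braycurtis")))


class TestNMDS:
    def test_embeddable_configuration_reaches_tiny_stress(self, rng):
        pts = rng.random((12, 2)) * 5
        res = nmds(_euclid_dm(pts), k=2, n_starts=8, seed=0)
        assert res.stress < 1e-3

    def test_duplicated_sample_lands_coincident(self, rng):
        pts = np.vstack([rng.random((6, 2)), [[0.3, 0.3]], [[0.3, 0.3]]])
        res = nmds(_euclid_dm(pts), k=2, n_starts=6, seed=0)
        assert np.linalg.norm(res.coordinates[-1] - res.coordinates[-2]) < 1e-2

    def test_stress_trace_monotone_nonincreasing(self, rng):
        pts = rng.random((10, 3))
        res = nmds(_euclid_dm(pts), k=2, n_starts=1, seed=3)
        trace = np.asarray(res.stress_trace)
        assert (np.diff(trace) <= 1e-9).all()

    def test_k_too_large_rejected(self):
        with pytest.raises(ValidationError):
            nmds(_dm(np.zeros((3, 3))), k=3)


class TestPermanova:
    def test_matches_vegan_sequential_decomposition(self, vegan_dm):
        res = permanova(vegan_dm, VEGAN_META, n_perm=49, seed=0)
        tab = res.table.set_index("factor")
        for f in ("subject", "diet", "day"):
            assert tab.loc[f, "SS"] == pytest.approx(VEGAN_SS[f], abs=1e-9)
            assert tab.loc[f, "R2"] == pytest.approx(VEGAN_R2[f], abs=1e-9)
            assert tab.loc[f, "F"] == pytest.approx(VEGAN_F[f], abs=1e-4)
        assert res.residual_ss == pytest.approx(VEGAN_RESID_SS, abs=1e-9)

    def test_r2_and_residual_sum_to_one(self, vegan_dm):
        res = permanova(vegan_dm, VEGAN_META, n_perm=9, seed=0)
        total = res.table["R2"].sum() + res.residual_ss / res.total_ss
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_extreme_separation_gives_smallest_p(self, rng):
        pts = np.vstack([rng.normal(0, 0.01, (6, 2)), rng.normal(50, 0.01, (6, 2))])
        groups = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 6})
        res = permanova(_euclid_dm(pts), groups, n_perm=199, seed=1)
        assert res.p("g") == pytest.approx(1 / 200)

    def test_constant_factor_rejected(self, vegan_dm):
        with pytest.raises(ValidationError):
            permanova(vegan_dm, pd.DataFrame({"g": ["x"] * 12}), n_perm=9)

    def test_seeded_p_values_reproducible(self, vegan_dm):
        p1 = permanova(vegan_dm, VEGAN_META, n_perm=49, seed=7).table["p"]
        p2 = permanova(vegan_dm, VEGAN_META, n_perm=49, seed=7).table["p"]
        assert (p1 == p2).all()

    def test_single_factor_euclidean_equals_classic_anova_f(self, rng):
        # one two-level factor on 1-D Euclidean distances reproduces the
        # one-way ANOVA F statistic
        y = np.concatenate([rng.normal(0, 1, 10), rng.normal(1.5, 1, 10)])
        groups = ["a"] * 10 + ["b"] * 10
        dm = _dm(np.abs(y[:, None] - y[None, :]))
        res = permanova(dm, pd.DataFrame({"g": groups}), n_perm=9, seed=0)
        F_classic, _ = anova_oneway(y, groups)
        assert res.table["F"].iloc[0] == pytest.approx(F_classic)


class TestBetadisper:
    def test_matches_vegan(self, vegan_dm):
        res = betadisper(vegan_dm, VEGAN_META["diet"])
        np.testing.assert_allclose(res.distances, VEGAN_DISPER_DISTANCES, atol=2e-4)
        assert res.F == pytest.approx(VEGAN_DISPER_F, abs=1e-3)
        assert res.p == pytest.approx(VEGAN_DISPER_P, abs=1e-3)

    def test_mirror_groups_have_equal_dispersion(self, rng):
        pts = rng.random((8, 2))
        mirrored = np.vstack([pts, pts + [100, 0]])
        res = betadisper(_euclid_dm(mirrored), ["a"] * 8 + ["b"] * 8)
        assert res.p > 0.95
        assert res.group_means["a"] == pytest.approx(res.group_means["b"])

    def test_inflated_group_detected(self, rng):
        pts = np.vstack([rng.normal(0, 1, (12, 2)), rng.normal(0, 3, (12, 2))])
        res = betadisper(_euclid_dm(pts), ["a"] * 12 + ["b"] * 12)
        assert res.p < 0.05

    def test_equal_distances_give_zero_f(self):
        # four points on a square, split into two groups of opposite corners
        pts = [[0, 0], [1, 1], [1, 0], [0, 1]]
        res = betadisper(_euclid_dm(pts), ["a", "a", "b", "b"])
        assert res.F == pytest.approx(0.0, abs=1e-10)

    def test_singleton_group_rejected(self, vegan_dm):
        with pytest.raises(ValidationError):
            betadisper(vegan_dm, ["a"] + ["b"] * 11)


class TestAnovaBH:
    def test_equal_group_means_give_zero_f(self):
        F, p = anova_oneway([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"][::-1])
        F2, _ = anova_oneway([1, 2, 1, 2], ["a", "a", "b", "b"])
        assert F2 == pytest.approx(0.0)

    def test_separated_groups_significant(self, rng):
        y = np.concatenate([rng.normal(0, 1, 20), rng.normal(5, 1, 20)])
        _, p = anova_oneway(y, ["a"] * 20 + ["b"] * 20)
        assert p < 0.001

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            anova_oneway([1, 2, 3], ["a", "a", "a"])

    def test_bh_step_up_by_hand(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_bh_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_bh_never_below_raw(self, rng):
        p = rng.random(50)
        assert (bh_adjust(p) >= p - 1e-15).all()

    def test_bh_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])
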