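import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from microdyn import (ValidationError, persistence_matrix, dtw_distance,
                      dtw_distance_matrix, pam, dtw_cluster,
                      persistence_abundance_fit, build_networks, edge_deltas,
                      edge_models, degree_centrality, cluster_rank_tests,
                      SyntheticDesign, generate, filter_rare, scale_counts)
from microdyn.persistence_dynamics import PersistenceMatrix
from microdyn.preprocess import NormalizedTable
from conftest import make_table


def _six_subject_table(counts_by_day, rng=None):
    """counts_by_day: dict day -> (n_asv, 6) array."""
    days = sorted(counts_by_day)
    cols, subjects, day_list = [], [], []
    for d in days:
        arr = np.asarray(counts_by_day[d])
        for s in range(arr.shape[1]):
            cols.append(arr[:, s])
            subjects.append(f"50{s:02d}")
            day_list.append(d)
    counts = np.column_stack(cols)
    counts[0] = np.maximum(counts[0], 1)  # no empty samples
    return make_table(counts, subjects, day_list)


class TestPersistenceMatrix:
    def test_ubiquitous_asv_constant_row_scales_to_zero(self):
        t = _six_subject_table({1: np.ones((2, 6)), 9: np.ones((2, 6))})
        pm = persistence_matrix(t)
        assert (pm.values[1] == 6).all()
        assert pm.scaled()[1] == pytest.approx([0.0, 0.0])

    def test_never_detected_asv_has_zero_row(self):
        arr = np.ones((3, 6), dtype=int)
        arr2 = arr.copy()
        arr[2] = 0
        arr2[2] = 0
        pm = persistence_matrix(_six_subject_table({1: arr, 9: arr2}))
        assert (pm.values[2] == 0).all()

    def test_matches_brute_force(self, rng):
        counts = rng.integers(0, 3, size=(30, 12))
        t = make_table(counts, [f"s{j % 4}" for j in range(12)],
                       [10 * (j // 4) + 1 for j in range(12)])
        pm = persistence_matrix(t, detection_threshold=2)
        for i in range(30):
            for k, day in enumerate(pm.days):
                expect = sum(1 for j, s in enumerate(t.samples)
                             if s.day == day and t.counts[i, j] >= 2)
                assert pm.values[i, k] == expect

    def test_entries_bounded_by_sampled_subjects(self, default_run):
        pm = persistence_matrix(default_run["filtered"])
        assert (pm.values <= pm.n_subjects_per_day[None, :]).all()


class TestDTW:
    def test_self_distance_zero(self, rng):
        x = rng.random(15)
        assert dtw_distance(x, x) == 0.0

    def test_warping_beats_euclidean_for_shifted_rows(self):
        x = np.zeros(15)
        x[5] = 3.0
        y = np.zeros(15)
        y[6] = 3.0
        assert dtw_distance(x, y) < np.linalg.norm(x - y)

    def test_matrix_matches_pairwise_calls(self, rng):
        rows = rng.random((7, 15))
        full = dtw_distance_matrix(rows)
        for i in range(7):
            for j in range(7):
                assert full[i, j] == pytest.approx(dtw_distance(rows[i], rows[j]))

    def test_pam_recovers_separated_blobs(self, rng):
        a = rng.normal(0, 0.2, (10, 4))
        b = rng.normal(5, 0.2, (12, 4))
        X = np.vstack([a, b])
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        labels = pam(D, 2, seed=0)
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]


class TestClustering:
    def test_planted_families_recovered(self, default_run):
        pm = persistence_matrix(default_run["filtered"])
        truth = [1 if a.startswith("ASV_S") else 0 for a in pm.asv_ids]
        ca = dtw_cluster(pm, seed=0)
        pred = [ca.labels[a] - 1 for a in pm.asv_ids]
        assert adjusted_rand_score(truth, pred) > 0.9

    def test_stable_cluster_is_the_persistent_one(self, default_run):
        pm = persistence_matrix(default_run["filtered"])
        ca = dtw_cluster(pm, seed=0)
        s = ca.summary.set_index("cluster")
        assert s.loc[2, "mean_persistence"] > s.loc[1, "mean_persistence"]

    def test_k_must_be_two(self, default_run):
        pm = persistence_matrix(default_run["filtered"])
        with pytest.raises(ValidationError):
            dtw_cluster(pm, k=3)

    def test_fewer_rows_than_clusters_rejected(self):
        pm = PersistenceMatrix(["a"], [1, 2], np.array([[1, 1]]), np.array([1, 1]))
        with pytest.raises(ValidationError):
            dtw_cluster(pm, k=2)


class TestPersistenceAbundance:
    def _pm_and_table(self, pers, abunds):
        n = len(pers)
        pm = PersistenceMatrix([f"A{i}" for i in range(n)], [1],
                               np.asarray(pers)[:, None], np.array([6]))
        t = make_table(np.ones((n, 2), dtype=int), ["x", "y"], [1, 2],
                       asv_ids=[f"A{i}" for i in range(n)])
        norm = NormalizedTable(list(pm.asv_ids), t.samples,
                               np.tile(np.asarray(abunds, float)[:, None], 2),
                               "scaled")
        return pm, norm

    def test_exact_line_recovered(self):
        pers = [0, 1, 2, 3, 4, 5, 6]
        # y = log(mean abundance + 1) = 2 * persistence fraction exactly
        x = np.array(pers) / 6
        abunds = np.exp(2 * x) - 1
        pm, norm = self._pm_and_table(pers, abunds)
        fit = persistence_abundance_fit(pm, norm)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_no_persistence_variance_rejected(self):
        pm, norm = self._pm_and_table([3, 3, 3], [1.0, 2.0, 3.0])
        with pytest.raises(ValidationError):
            persistence_abundance_fit(pm, norm)

    def test_planted_coupling_positive_on_default_design(self, default_run):
        pm = persistence_matrix(default_run["filtered"])
        scaled = scale_counts(default_run["filtered"])
        fit = persistence_abundance_fit(pm, scaled)
        assert fit.slope > 0 and fit.ci_low > 0


class TestNetworks:
    def test_snapshot_count_and_edge_rule(self, default_run):
        nets = build_networks(default_run["filtered"])
        assert len(nets) == 15
        pm = persistence_matrix(default_run["filtered"])
        for snap, k in zip(sorted(nets, key=lambda s: s.day), range(15)):
            # total edges at t equal the persistence column sum
            assert snap.n_edges == pm.values[:, k].sum()

    def test_subject_with_empty_profile_is_isolated(self):
        counts = np.array([[5, 0], [3, 0]])
        counts[0, 1] = 0
        t = make_table(np.array([[5, 1], [3, 0]]), ["a", "b"], [1, 1])
        (snap,) = build_networks(t, detection_threshold=2)
        assert all(s != "b" for s, _ in snap.edges)
        assert "b" in snap.subjects

    def test_gaining_one_asv_counts_one_formed_edge(self):
        t = make_table(np.array([[5, 5], [0, 4]]), ["a", "a"], [1, 9])
        deltas = edge_deltas(build_networks(t))
        row = deltas.frame.iloc[0]
        assert (row["formed"], row["destroyed"]) == (1, 0)

    def test_identical_snapshots_give_zero_deltas(self):
        t = make_table(np.array([[5, 5], [2, 2]]), ["a", "a"], [1, 9])
        deltas = edge_deltas(build_networks(t))
        assert (deltas.frame[["formed", "destroyed"]] == 0).all().all()

    def test_edge_bookkeeping_identity(self, default_run):
        nets = sorted(build_networks(default_run["filtered"]),
                      key=lambda s: s.day)
        deltas = edge_deltas(nets).frame.set_index(["subject_id", "day"])
        for prev, cur in zip(nets[:-1], nets[1:]):
            for subj in prev.subjects & cur.subjects:
                e_prev = sum(1 for s, _ in prev.edges if s == subj)
                e_cur = sum(1 for s, _ in cur.edges if s == subj)
                row = deltas.loc[(subj, cur.day)]
                assert e_cur == e_prev + row["formed"] - row["destroyed"]


class TestEdgeModels:
    def test_null_design_jump_ci_covers_zero(self):
        d = SyntheticDesign(isolation_end_jump=0.0, seed=91)
        table, _ = generate(d, with_tree=False)
        em = edge_models(edge_deltas(build_networks(filter_rare(table))))
        post = em["formed"].coef("post_isolation")
        assert abs(post["b"]) < 2.5 * post["SE"]

    def test_planted_decline_gives_negative_day_slope(self):
        hits = 0
        for seed in range(4):
            d = SyntheticDesign(isolation_end_jump=0.0, seed=400 + seed)
            table, _ = generate(d, with_tree=False)
            em = edge_models(edge_deltas(build_networks(filter_rare(table))))
            hits += em["formed"].coef("day")["b"] < 0
        assert hits >= 3

    def test_churn_independence_under_stationary_null(self):
        # independent gain/loss switches: formed and destroyed uncorrelated
        ok = 0
        for seed in range(5):
            d = SyntheticDesign(isolation_end_jump=0.0,
                                churn_decline_per_day=0.0, seed=500 + seed)
            table, _ = generate(d, with_tree=False)
            deltas = edge_deltas(build_networks(filter_rare(table)))
            ok += abs(deltas.spearman_rho) < 0.2
        assert ok >= 4


class TestCentrality:
    def test_degree_values(self):
        t = make_table(np.array([[1, 1, 1], [0, 1, 0], [0, 0, 0]]),
                       ["a", "b", "c"], [1, 1, 1])
        cen = degree_centrality(build_networks(t))
        by = cen.set_index("asv_id")["degree"]
        assert by["ASV0"] == 3 and by["ASV1"] == 1 and by["ASV2"] == 0

    def test_stable_cluster_more_central_at_every_timepoint(self, default_run):
        filtered = default_run["filtered"]
        pm = persistence_matrix(filtered)
        ca = dtw_cluster(pm, seed=0)
        cen = degree_centrality(build_networks(filtered))
        tests = cluster_rank_tests(cen, ca)
        assert (tests["median_stable"] > tests["median_inconsistent"]).all()
        assert (tests["p"] < 0.01).all()
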