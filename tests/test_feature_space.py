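"""Embedding, clustering, selectivity, recovery ratios, trajectories."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import reachscore as rs
from reachscore import grammar
from reachscore.feature_space import (RECOVERY_EPSILON, recovery_ratios,
                                      trajectory_dtw, trajectory_xcorr_max,
                                      compare_session_reproducibility)
from reachscore.relevance import FeatureImportance


class TestTopFeatureSelection:
    def test_one_hot_importance(self):
        imp = np.zeros(16)
        imp[7] = 1.0
        assert rs.select_top_features(imp, k=1).tolist() == [7]

    def test_k_equals_f_returns_all(self):
        sel = rs.select_top_features(np.arange(10, dtype=float), k=10)
        assert sel.tolist() == list(range(10))

    def test_ties_break_to_lower_index(self):
        imp = np.array([1.0, 2.0, 2.0, 0.5])
        assert rs.select_top_features(imp, k=2).tolist() == [1, 2]
        imp = np.ones(6)
        assert rs.select_top_features(imp, k=3).tolist() == [0, 1, 2]

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            rs.select_top_features(np.ones(4), k=0)
        with pytest.raises(ValueError):
            rs.select_top_features(np.ones(4), k=5)

    def test_accepts_feature_importance_object(self):
        fi = FeatureImportance(importance=np.array([0.1, 5.0, 0.2]), n_clips=1)
        assert rs.select_top_features(fi, k=1).tolist() == [1]


class TestProjection:
    def test_pc1_aligns_with_dominant_axis(self, rng):
        """Eigen-oracle: variance concentrated on one axis -> PC1 along it."""
        n = 500
        x = np.zeros((n, 6))
        x[:, 2] = rng.normal(0, 5.0, n)     # dominant direction
        x += rng.normal(0, 0.1, (n, 6))
        model = rs.fit_projection(x, np.arange(6), n_components=3)
        cos = abs(model.components[0, 2])
        assert cos > 0.99
        assert model.explained[0] > model.explained[1] > model.explained[2]

    def test_center_maps_to_origin(self, rng):
        x = rng.normal(3.0, 1.0, (50, 5))
        model = rs.fit_projection(x, np.arange(5), n_components=2)
        z = rs.apply_projection(model, model.center[None])
        np.testing.assert_allclose(z, 0.0, atol=1e-9)

    def test_pls_separates_constructed_groups(self, rng):
        n = 200
        y = np.repeat([0, 1], n // 2)
        x = rng.normal(0, 0.3, (n, 8))
        x[:, 4] += 3.0 * y                   # group contrast on one feature
        model = rs.fit_projection(x, np.arange(8), method="pls",
                                  n_components=2, group_labels=y)
        z = rs.apply_projection(model, x)[:, 0]
        lo, hi = z[y == 0], z[y == 1]
        if lo.mean() > hi.mean():
            lo, hi = hi, lo
        assert lo.max() < hi.min()          # zero overlap on component 1

    def test_pls_requires_groups(self, rng):
        with pytest.raises(ValueError, match="group"):
            rs.fit_projection(rng.normal(size=(30, 4)), np.arange(4),
                              method="pls")

    def test_rotation_equivariance(self, rng):
        """Rigidly rotating the input rotates scores; pairwise distances in
        the embedding are preserved."""
        x = rng.normal(0, 1, (100, 5)) @ np.diag([3, 2, 1.5, 1, 0.5])
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        ma = rs.fit_projection(x, np.arange(5), n_components=3)
        mb = rs.fit_projection(x @ q, np.arange(5), n_components=3)
        za, zb = rs.apply_projection(ma, x), rs.apply_projection(mb, x @ q)
        da = np.linalg.norm(za[:, None] - za[None], axis=-1)
        db = np.linalg.norm(zb[:, None] - zb[None], axis=-1)
        np.testing.assert_allclose(da, db, atol=1e-9)


class TestClustering:
    def test_planted_blobs_recovered(self, rng):
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        labels = rng.integers(0, 3, 300)
        x = centers[labels] + rng.normal(0, 0.5, (300, 2))
        cm = rs.cluster_frames(x, k=3, seed=0)
        assert adjusted_rand_score(labels, cm.assignments) > 0.95

    def test_seeded_determinism(self, rng):
        x = rng.normal(size=(100, 4))
        a = rs.cluster_frames(x, k=5, seed=3)
        b = rs.cluster_frames(x, k=5, seed=3)
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(ValueError):
            rs.cluster_frames(rng.normal(size=(5, 2)), k=10)

    def test_group_counts_populate_stats(self, rng):
        x = np.r_[rng.normal(0, 0.1, (20, 2)), rng.normal(5, 0.1, (20, 2))]
        g = np.r_[np.ones(20), np.zeros(20)]
        cm = rs.cluster_frames(x, k=2, seed=0, group_labels=g)
        assert set(cm.stats["selectivity"].round(6)) == {1.0, -1.0}


class TestSelectivityIndex:
    @pytest.mark.parametrize("ns,nc,expected", [
        (10, 0, 1.0),     # purely stroke frames
        (5, 5, 0.0),      # balanced
        (3, 1, 0.5),
        (0, 10, -1.0),
    ])
    def test_values(self, ns, nc, expected):
        assert rs.selectivity_index(ns, nc) == pytest.approx(expected)

    def test_empty_cluster_undefined(self):
        with pytest.raises(ValueError):
            rs.selectivity_index(0, 0)

    @given(ns=st.integers(0, 10_000), nc=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=100)
    def test_bounds_and_antisymmetry(self, ns, nc):
        if ns + nc == 0:
            return
        v = rs.selectivity_index(ns, nc)
        assert -1.0 <= v <= 1.0
        assert v == pytest.approx(-rs.selectivity_index(nc, ns))


class TestCategoryAssignment:
    def _cluster(self, embedding, assignments, k):
        from reachscore.feature_space import ClusterModel
        centers = np.stack([embedding[assignments == j].mean(axis=0)
                            for j in range(k)])
        return ClusterModel(k=k, centers=centers, assignments=assignments,
                            inertia=0.0)

    def test_quorum_met_assigns_modal_category(self, rng):
        emb = rng.normal(size=(8, 2)) * 0.01
        cm = self._cluster(emb, np.zeros(8, int), 1)
        labels = np.array(["lift"] * 5 + ["aim"] * 3)
        cats = rs.assign_categories(cm, emb, labels)
        assert cats[0] == "lift"

    def test_tie_at_quorum_is_not_clear(self, rng):
        emb = rng.normal(size=(8, 2)) * 0.01
        cm = self._cluster(emb, np.zeros(8, int), 1)
        labels = np.array(["lift"] * 4 + ["aim"] * 4)
        assert rs.assign_categories(cm, emb, labels)[0] == grammar.NOT_CLEAR

    def test_below_quorum_is_not_clear(self, rng):
        emb = rng.normal(size=(8, 2)) * 0.01
        cm = self._cluster(emb, np.zeros(8, int), 1)
        labels = np.array(["lift", "aim", "grasp", "eat"] * 2)
        assert rs.assign_categories(cm, emb, labels)[0] == grammar.NOT_CLEAR

    def test_small_cluster_uses_all_members(self, rng):
        emb = rng.normal(size=(5, 2)) * 0.01
        cm = self._cluster(emb, np.zeros(5, int), 1)
        labels = np.array(["grasp"] * 5)
        assert rs.assign_categories(cm, emb, labels, n_probe=8)[0] == "grasp"


class TestDayProbabilities:
    def test_probabilities_sum_to_one_per_day(self, rng):
        from reachscore.feature_space import ClusterModel
        n = 200
        assignments = rng.integers(0, 6, n)
        days = rng.choice([-1, 1, 6], n)
        cm = ClusterModel(k=6, centers=np.zeros((6, 2)),
                          assignments=assignments, inertia=0.0)
        probs = rs.day_probabilities(cm, days)
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-12)

    def test_single_cluster_has_unit_probability(self):
        from reachscore.feature_space import ClusterModel
        cm = ClusterModel(k=1, centers=np.zeros((1, 2)),
                          assignments=np.zeros(30, int), inertia=0.0)
        probs = rs.day_probabilities(cm, np.repeat([1, 6, 15], 10))
        assert (probs.loc[0] == 1.0).all()


class TestRecoveryRatios:
    def test_equal_probabilities_give_unity(self):
        prof = recovery_ratios(0.2, 0.2, 0.2)
        assert prof.m1[0] == pytest.approx(1.0)

    def test_stated_epsilon_arithmetic(self):
        """p1 = 0.2, p0 = 0 -> M1 = 0.2001 / 0.0001 = 2001."""
        prof = recovery_ratios(0.0, 0.2, 0.0)
        assert prof.m1[0] == pytest.approx(2001.0)
        assert prof.epsilon == RECOVERY_EPSILON == 1e-4

    def test_lost_vs_novel_sides(self):
        lost = recovery_ratios(0.3, 0.0, 0.05)
        novel = recovery_ratios(0.0, 0.3, 0.1)
        assert lost.m1[0] < 1 < novel.m1[0]


class TestTrajectorySimilarity:
    def _traj(self, rng, t=125, d=7):
        return np.cumsum(rng.normal(size=(t, d)), axis=0)

    def test_identity(self, rng):
        a = self._traj(rng)
        v, lag = trajectory_xcorr_max(a, a)
        assert v == pytest.approx(1.0)
        assert lag == 0
        assert trajectory_dtw(a, a) == pytest.approx(0.0)

    def test_circular_shift_recovered(self, rng):
        a = self._traj(rng)
        flat = a[:, :7].T.reshape(-1)
        shift = 40
        b_flat = np.roll(flat, shift)
        b = b_flat.reshape(7, -1).T
        v, lag = trajectory_xcorr_max(a, b)
        assert v == pytest.approx(1.0)
        assert lag in (shift, flat.size - shift)

    def test_dtw_forgives_time_warp(self, rng):
        t = np.linspace(0, 2 * np.pi, 60)
        a = np.stack([np.sin(t), np.cos(t)], axis=1)
        warped = np.interp(np.linspace(0, 1, 60) ** 1.3,
                           np.linspace(0, 1, 60), t)
        b = np.stack([np.sin(warped), np.cos(warped)], axis=1)
        naive = float(np.linalg.norm(a - b, axis=1).sum())
        assert trajectory_dtw(a, b, n_components=2) < 0.5 * naive

    def test_component_budget_enforced(self, rng):
        a = self._traj(rng, d=3)
        with pytest.raises(ValueError, match="n_components"):
            trajectory_xcorr_max(a, a, n_components=7)

    def test_reproducibility_test_detects_planted_difference(self, rng):
        pre = rng.normal(0.8, 0.05, 200)
        post = rng.normal(0.5, 0.15, 200)
        rep = compare_session_reproducibility(pre, post)
        assert rep["p_t"] < 0.01 and rep["p_u"] < 0.01


class TestEllipseFit:
    def _ellipse_points(self, a, b, theta, cx, cy, n=40):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        x = a * np.cos(t)
        y = b * np.sin(t)
        c, s = np.cos(theta), np.sin(theta)
        return np.stack([cx + c * x - s * y, cy + s * x + c * y], axis=1)

    def test_known_ellipse_recovered_to_one_percent(self):
        pts = self._ellipse_points(3.0, 1.5, 0.4, 2.0, -1.0)
        fit = rs.fit_ellipse(pts)
        assert fit["center"][0] == pytest.approx(2.0, rel=0.01)
        assert fit["center"][1] == pytest.approx(-1.0, rel=0.01)
        assert fit["axes"][0] == pytest.approx(3.0, rel=0.01)
        assert fit["axes"][1] == pytest.approx(1.5, rel=0.01)

    def test_circle_has_equal_axes(self):
        pts = self._ellipse_points(2.0, 2.0, 0.0, 0.0, 0.0)
        fit = rs.fit_ellipse(pts)
        assert fit["axes"][0] == pytest.approx(fit["axes"][1], rel=1e-6)
        assert fit["axes"][0] == pytest.approx(2.0, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            rs.fit_ellipse(np.zeros((4, 2)))

    def test_collinear_points_rejected(self):
        pts = np.stack([np.arange(6), 2 * np.arange(6)], axis=1).astype(float)
        with pytest.raises(ValueError):
            rs.fit_ellipse(pts)
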