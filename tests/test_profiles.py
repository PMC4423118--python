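"""Ratio matrices, masked k-means, cluster profiles, TSS scores, correlation."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from ndrscope.annotation import PromoterFrame
from ndrscope.profiles import (cluster_mean_profiles, correlate_assays,
                               kmeans_profiles, ratio_matrix, tss_score)
from ndrscope.tracks import WindowMatrix


def make_matrix(scores, mask=None, frame=None, scale="linear"):
    scores = np.asarray(scores, dtype=float)
    frame = frame or PromoterFrame(flank=scores.shape[1] * 25, window=50)
    if mask is None:
        mask = np.isfinite(scores)
    ids = [f"g{i}" for i in range(len(scores))]
    return WindowMatrix(ids, scores, mask, frame, scale)


class TestRatioMatrix:
    def test_equal_inputs_give_zero(self):
        m = make_matrix(np.random.default_rng(0).uniform(1, 2, (4, 8)))
        r = ratio_matrix(m, m)
        np.testing.assert_allclose(r.scores[r.mask], 0.0, atol=1e-12)
        assert r.scale == "log2_ratio"

    def test_doubling_is_about_plus_one(self):
        rng = np.random.default_rng(1)
        w = make_matrix(rng.uniform(1, 2, (4, 8)))
        m = make_matrix(2 * w.scores)
        r = ratio_matrix(m, w)
        assert np.all(np.abs(r.scores[r.mask] - 1.0) < 0.15)

    def test_swap_negates_valid_cells(self):
        rng = np.random.default_rng(2)
        a = make_matrix(rng.uniform(0.5, 3, (5, 8)))
        b = make_matrix(rng.uniform(0.5, 3, (5, 8)))
        np.testing.assert_allclose(ratio_matrix(a, b).scores,
                                   -ratio_matrix(b, a).scores,
                                   atol=1e-9)

    def test_joint_mask(self):
        a = make_matrix([[1.0, 2.0, np.nan, 4.0]],
                        frame=PromoterFrame(flank=100, window=50))
        b = make_matrix([[1.0, np.nan, 3.0, 4.0]],
                        frame=PromoterFrame(flank=100, window=50))
        r = ratio_matrix(a, b)
        np.testing.assert_array_equal(r.mask[0], [True, False, False, True])

    def test_log2_input_rejected(self):
        m = make_matrix(np.ones((3, 4)), scale="log2_ratio",
                        frame=PromoterFrame(flank=100, window=50))
        with pytest.raises(ValueError, match="linear"):
            ratio_matrix(m, m)


class TestKmeans:
    def test_k1_centroid_is_columnwise_mean(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(12, 8))
        scores[2, 3] = np.nan
        m = make_matrix(scores, scale="log2_ratio")
        res = kmeans_profiles(m, k=1, seed=0, restarts=3)
        assert set(res.assignments.values()) == {0}
        np.testing.assert_allclose(res.centroids[0],
                                   np.nanmean(scores, axis=0), atol=1e-9)

    def test_planted_two_archetypes_recovered_exactly(self):
        rng = np.random.default_rng(4)
        a = np.array([2.0, 2.0, -2.0, -2.0, 0.0, 0.0, 1.0, -1.0])
        b = -a
        noise_sd = 0.2  # separation |a-b| >> 3 x noise SD
        profiles = np.vstack([a + rng.normal(0, noise_sd, 8) for _ in range(20)]
                             + [b + rng.normal(0, noise_sd, 8) for _ in range(20)])
        m = make_matrix(profiles, scale="log2_ratio")
        res = kmeans_profiles(m, k=2, seed=1, restarts=10)
        labels = res.labels_for(m.gene_ids)
        truth = [0] * 20 + [1] * 20
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_matches_exhaustive_partition_optimum_1d(self):
        """Attained inertia equals the best of all 2-block partitions."""
        rng = np.random.default_rng(5)
        frame = PromoterFrame(flank=25, window=50)
        for _ in range(20):
            pts = rng.uniform(-3, 3, size=6)
            m = make_matrix(pts[:, None], frame=frame, scale="log2_ratio")
            res = kmeans_profiles(m, k=2, seed=0, restarts=50)
            best = np.inf
            for r in range(1, 6):
                for subset in itertools.combinations(range(6), r):
                    in_a = np.zeros(6, dtype=bool)
                    in_a[list(subset)] = True
                    inertia = sum(((pts[sel] - pts[sel].mean()) ** 2).sum()
                                  for sel in (in_a, ~in_a) if sel.any())
                    best = min(best, inertia)
            assert res.inertia <= best + 1e-9

    def test_agrees_with_sklearn_on_fully_valid_matrix(self):
        """Independent cross-check: same inertia as scikit-learn KMeans."""
        from sklearn.cluster import KMeans
        rng = np.random.default_rng(6)
        centers = np.array([[-5.0], [0.0], [5.0]]) * np.ones((1, 8))
        X = np.vstack([c + rng.normal(0, 0.3, (15, 8)) for c in centers])
        m = make_matrix(X, scale="log2_ratio")
        ours = kmeans_profiles(m, k=3, seed=2, restarts=20)
        sk = KMeans(n_clusters=3, n_init=20, random_state=2).fit(X)
        assert abs(ours.inertia - sk.inertia_) / sk.inertia_ < 1e-9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        m = make_matrix(rng.normal(size=(30, 8)), scale="log2_ratio")
        r1 = kmeans_profiles(m, k=3, seed=9, restarts=5)
        r2 = kmeans_profiles(m, k=3, seed=9, restarts=5)
        assert r1.assignments == r2.assignments
        np.testing.assert_array_equal(r1.centroids, r2.centroids)

    def test_row_permutation_permutes_assignments(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(-3, 0.3, (10, 8)),
                       rng.normal(3, 0.3, (10, 8))])
        m1 = make_matrix(X, scale="log2_ratio")
        perm = rng.permutation(20)
        m2 = WindowMatrix([f"g{i}" for i in perm], X[perm],
                          np.isfinite(X[perm]), m1.frame, "log2_ratio")
        r1 = kmeans_profiles(m1, k=2, seed=3, restarts=10)
        r2 = kmeans_profiles(m2, k=2, seed=3, restarts=10)
        # same genes -> same clusters (ids are stable via NDR-zone ordering)
        agree = [r1.assignments[g] == r2.assignments[g] for g in r1.assignments]
        assert all(agree)

    def test_low_validity_genes_set_aside(self):
        X = np.ones((5, 8))
        mask = np.ones((5, 8), dtype=bool)
        mask[0, :5] = False  # 3/8 valid < 50%
        m = make_matrix(X, mask=mask, scale="log2_ratio")
        res = kmeans_profiles(m, k=1, seed=0, restarts=2)
        assert res.assignments["g0"] == -1
        assert res.unclustered == ["g0"]

    def test_k_too_large_is_error(self):
        m = make_matrix(np.ones((3, 8)), scale="log2_ratio")
        with pytest.raises(ValueError):
            kmeans_profiles(m, k=5, seed=0)


class TestClusterMeanProfiles:
    def test_identical_rows_zero_width_band(self):
        row = np.arange(8.0)
        m = make_matrix(np.tile(row, (12, 1)), scale="log2_ratio")
        res = kmeans_profiles(m, k=1, seed=0, restarts=2)
        profs = cluster_mean_profiles(m, res, n_boot=100, seed=0)
        np.testing.assert_allclose(profs[0]["mean"], row)
        np.testing.assert_allclose(profs[0]["lo"], row)
        np.testing.assert_allclose(profs[0]["hi"], row)

    def test_weighted_mean_identity(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(0, 0.1, (15, 8)),
                       rng.normal(5, 0.1, (25, 8))])
        m = make_matrix(X, scale="log2_ratio")
        res = kmeans_profiles(m, k=2, seed=0, restarts=5)
        profs = cluster_mean_profiles(m, res, n_boot=50, seed=0)
        weighted = sum(profs[c]["mean"] * profs[c]["n_genes"] for c in profs)
        weighted /= sum(profs[c]["n_genes"] for c in profs)
        np.testing.assert_allclose(weighted, X.mean(axis=0), atol=1e-9)

    def test_low_support_flagged(self):
        X = np.ones((5, 8))
        m = make_matrix(X, scale="log2_ratio")
        res = kmeans_profiles(m, k=1, seed=0, restarts=2)
        profs = cluster_mean_profiles(m, res, n_boot=20, seed=0, min_genes=10)
        assert profs[0]["low_support"].all()


class TestTssScore:
    def test_constant_matrix_mean(self, frame):
        m = make_matrix(np.full((3, 32), 2.5), frame=frame)
        scores = tss_score(m, "mean")
        assert all(v == 2.5 for v in scores.values())

    def test_single_valid_window_max(self, frame):
        scores_arr = np.full((1, 32), np.nan)
        col = list(frame.window_offsets()).index(0)
        scores_arr[0, col] = 7.0
        m = make_matrix(scores_arr, frame=frame)
        assert tss_score(m, "max")["g0"] == 7.0

    def test_matches_naive_recomputation(self, frame):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(50, 32))
        X[rng.random((50, 32)) < 0.2] = np.nan
        m = make_matrix(X, frame=frame)
        got = tss_score(m, "mean", half_width=250)
        starts = frame.window_offsets()
        in_range = (starts < 250) & (starts + 50 > -250)
        for i, g in enumerate(m.gene_ids):
            vals = X[i][in_range & np.isfinite(X[i])]
            if vals.size:
                assert got[g] == pytest.approx(vals.mean(), abs=1e-12)
            else:
                assert np.isnan(got[g])

    def test_half_width_beyond_flank_error(self, frame):
        m = make_matrix(np.ones((2, 32)), frame=frame)
        with pytest.raises(ValueError):
            tss_score(m, "mean", half_width=900)


class TestCorrelateAssays:
    def test_identity_r_one(self):
        s = {f"g{i}": float(i) for i in range(10)}
        rep = correlate_assays(s, s)
        assert rep["r"] == pytest.approx(1.0)
        assert rep["slope"] == pytest.approx(1.0)

    def test_negated_r_minus_one(self):
        s = {f"g{i}": float(i) for i in range(10)}
        t = {g: -v + 3 for g, v in s.items()}
        rep = correlate_assays(s, t)
        assert rep["r"] == pytest.approx(-1.0)
        assert rep["slope"] == pytest.approx(-1.0)
        assert rep["intercept"] == pytest.approx(3.0)

    def test_bivariate_normal_rho(self):
        rng = np.random.default_rng(11)
        n = 2000
        x = rng.normal(size=n)
        y = 0.6 * x + np.sqrt(1 - 0.36) * rng.normal(size=n)
        a = {f"g{i}": x[i] for i in range(n)}
        b = {f"g{i}": y[i] for i in range(n)}
        rep = correlate_assays(a, b)
        assert rep["r"] == pytest.approx(0.6, abs=0.04)
        assert rep["n"] == n

    def test_zero_variance_undefined(self):
        a = {f"g{i}": 1.0 for i in range(5)}
        b = {f"g{i}": float(i) for i in range(5)}
        rep = correlate_assays(a, b)
        assert not rep["defined"] and np.isnan(rep["r"])
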