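import numpy as np
import pytest
from scipy.spatial.distance import pdist

from helpers import euclidean_dm, sorted_pairwise

from psma.errors import NumericalError, ValidationError
from psma.metricspace import similarity_to_distance
from psma.projection import (kruskal_mds, pcooa, project, sammon, shepard,
                             stress, tsne)
from psma.synth import generate_clusters


def brute_force_stress(d_matrix, coords, kind):
    """Independent double-loop evaluation of both stress formulas."""
    m = len(coords)
    num = denom = 0.0
    for i in range(m):
        for j in range(i + 1, m):
            d = d_matrix[i, j]
            dhat = np.hypot(*(np.asarray(coords[i]) - np.asarray(coords[j]))) \
                if len(coords[i]) == 2 else np.linalg.norm(
                    np.asarray(coords[i]) - np.asarray(coords[j]))
            if kind == "kruskal":
                num += (d - dhat) ** 2
                denom += d ** 2
            else:
                num += (d - dhat) ** 2 / d
                denom += d
    return np.sqrt(num / denom) if kind == "kruskal" else num / denom


class TestPCooA:
    def test_345_triangle_is_exact_isometry(self, triangle_345):
        pts, dm = triangle_345
        res = pcooa(dm, dims=2)
        np.testing.assert_allclose(sorted_pairwise(res.coords),
                                   sorted_pairwise(pts), atol=1e-9)

    def test_planar_cloud_is_exact_isometry(self, planar_cloud):
        pts, dm = planar_cloud
        res = pcooa(dm, dims=2)
        np.testing.assert_allclose(sorted_pairwise(res.coords),
                                   sorted_pairwise(pts), atol=1e-9)

    def test_collinear_points_recover_the_line(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10)])
        res = pcooa(euclidean_dm(pts), dims=1)
        np.testing.assert_allclose(np.sort(np.diff(np.sort(res.coords[:, 0]))),
                                   np.ones(9), atol=1e-9)
        # second eigenvalue is numerically zero
        assert abs(res.eigenvalues[1]) < 1e-9 * res.eigenvalues[0]

    def test_regular_simplex_equal_eigenvalues(self):
        from psma.metricspace import DistanceMatrix
        m = 5
        values = np.ones((m, m)) - np.eye(m)
        dm = DistanceMatrix([f"p{i}" for i in range(m)], values)
        res = pcooa(dm, dims=2)
        lam = res.eigenvalues[:m - 1]
        np.testing.assert_allclose(lam, lam[0], rtol=1e-9)

    def test_equilateral_triangle_projected_distances_equal(self):
        from psma.metricspace import DistanceMatrix
        values = np.ones((3, 3)) - np.eye(3)
        dm = DistanceMatrix(["a", "b", "c"], values)
        res = pcooa(dm, dims=2)
        proj_d = pdist(res.coords)
        np.testing.assert_allclose(proj_d, 1.0, rtol=1e-9)

    def test_deterministic_sign_convention(self, planar_cloud):
        _, dm = planar_cloud
        a, b = pcooa(dm), pcooa(dm)
        np.testing.assert_array_equal(a.coords, b.coords)
        for col in range(2):
            pivot = np.argmax(np.abs(a.coords[:, col]))
            assert a.coords[pivot, col] > 0

    def test_too_few_positive_eigenvalues_is_error(self):
        pts = np.column_stack([np.arange(4.0), np.zeros(4)])
        with pytest.raises(NumericalError, match="positive eigenvalues"):
            pcooa(euclidean_dm(pts), dims=2)

    def test_eigenvalues_descending(self, planar_cloud):
        _, dm = planar_cloud
        lam = pcooa(dm).eigenvalues
        assert (np.diff(lam) <= 1e-9).all()


class TestStressFunctions:
    def test_perfect_configuration_zero_stress(self, planar_cloud):
        pts, dm = planar_cloud
        assert stress(dm, pts, "kruskal") == pytest.approx(0.0, abs=1e-12)
        assert stress(dm, pts, "sammon") == pytest.approx(0.0, abs=1e-12)

    def test_doubled_coords_match_brute_force(self, triangle_345):
        pts, dm = triangle_345
        for kind in ("kruskal", "sammon"):
            expected = brute_force_stress(dm.values, 2 * pts, kind)
            assert stress(dm, 2 * pts, kind) == pytest.approx(expected, rel=1e-12)
        assert stress(dm, 2 * pts, "kruskal") > 0

    def test_swapped_pair_on_a_line_hand_value(self):
        pts = np.column_stack([np.arange(4.0), np.zeros(4)])
        dm = euclidean_dm(pts)
        swapped = pts.copy()
        swapped[[2, 3]] = swapped[[3, 2]]
        # hand evaluation over the 6 pairs:
        # originals  d  = {1,2,3,1,2,1}; swapped dhat = {1,3,2,2,1,1}
        # residuals (d-dhat)^2 = {0,1,1,1,1,0}; sum d^2 = 1+4+9+1+4+1 = 20
        expected = np.sqrt(4 / 20)
        assert stress(dm, swapped, "kruskal") == pytest.approx(expected, rel=1e-12)

    def test_size_mismatch_is_error(self, triangle_345):
        _, dm = triangle_345
        with pytest.raises(ValidationError):
            stress(dm, np.zeros((5, 2)))

    def test_stress_scale_invariance(self, planar_cloud):
        # scaling all distances and coords by c>0 leaves both normalized
        # stress values unchanged, so the minimizing shape is scale-free
        pts, dm = planar_cloud
        noisy = pts + np.random.default_rng(0).normal(0, 0.05, pts.shape)
        scaled_dm = euclidean_dm(3.0 * pts)
        for kind in ("sammon", "kruskal"):
            base = stress(dm, noisy, kind)
            assert stress(scaled_dm, 3.0 * noisy, kind) == pytest.approx(
                base, rel=1e-9)


class TestShepard:
    def test_perfect_configuration_r2_one(self, planar_cloud):
        pts, dm = planar_cloud
        assert shepard(dm, pts).r2 == pytest.approx(1.0, abs=1e-12)

    def test_shuffled_rows_destroy_r2(self, planar_cloud):
        pts, dm = planar_cloud
        shuffled = pts[np.random.default_rng(3).permutation(len(pts))]
        assert shepard(dm, shuffled).r2 < 0.3

    def test_r2_equals_squared_pearson(self, planar_cloud):
        pts, dm = planar_cloud
        noisy = pts + np.random.default_rng(5).normal(0, 0.2, pts.shape)
        data = shepard(dm, noisy)
        x, y = data.original_d, data.projected_d
        # independent textbook formula
        r = (((x - x.mean()) * (y - y.mean())).sum()
             / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert data.r2 == pytest.approx(r ** 2, rel=1e-12)
        assert len(x) == len(pts) * (len(pts) - 1) // 2


class TestKruskalMDS:
    def test_perfect_init_keeps_zero_stress(self, planar_cloud):
        pts, dm = planar_cloud
        res = kruskal_mds(dm, init=pts)
        assert res.stress == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(sorted_pairwise(res.coords),
                                   sorted_pairwise(pts), atol=1e-8)

    def test_monotone_transform_of_distances_still_fits(self, planar_cloud):
        pts, dm = planar_cloud
        gdm = euclidean_dm(pts)
        gdm.values[:] = np.sqrt(dm.values)  # monotone distortion, ranks intact
        res = kruskal_mds(gdm, max_iter=200)
        assert res.stress < 0.05

    def test_descent_from_random_start(self, planar_cloud):
        pts, dm = planar_cloud
        rng = np.random.default_rng(0)
        random_init = rng.normal(size=pts.shape)
        res = kruskal_mds(dm, init=random_init, max_iter=100)
        assert res.stress_trace[-1] < res.stress_trace[0]
        assert (np.diff(res.stress_trace) <= 1e-15).all()

    def test_too_few_points_is_error(self):
        dm = euclidean_dm(np.array([[0.0, 0], [1, 0], [2, 0]]))
        with pytest.raises(ValidationError, match=">=4"):
            kruskal_mds(dm)

    def test_zero_distance_ties_jittered_with_warning(self):
        pts = np.array([[0.0, 0], [0, 0], [3, 0], [0, 4], [2, 2]])
        dm = euclidean_dm(pts)
        with pytest.warns(UserWarning, match="jittered"):
            kruskal_mds(dm, max_iter=5)


class TestSammon:
    def test_perfect_init_zero_stress(self, planar_cloud):
        pts, dm = planar_cloud
        res = sammon(dm, init=pts)
        assert res.stress == pytest.approx(0.0, abs=1e-12)

    def test_stress_matches_brute_force_on_4_points(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1], [2, 2]])
        dm = euclidean_dm(pts)
        init = pts + np.random.default_rng(1).normal(0, 0.3, pts.shape)
        res = sammon(dm, init=init, max_iter=3, tol=0.0)
        expected = brute_force_stress(dm.values, res.coords, "sammon")
        assert res.stress == pytest.approx(expected, rel=1e-10)

    def test_descent_trace_non_increasing(self, planar_cloud):
        pts, dm = planar_cloud
        init = np.random.default_rng(2).normal(size=pts.shape)
        res = sammon(dm, init=init, max_iter=60)
        assert (np.diff(res.stress_trace) <= 0).all()
        assert res.stress < brute_force_stress(dm.values, init, "sammon")


class TestTSNE:
    def test_separated_clusters_stay_separable(self):
        data = generate_clusters(20, 20, separation=10.0, noise_sd=1.0, seed=4)
        dist = similarity_to_distance(data.similarity)
        res = tsne(dist, perplexity=10, seed=0)
        from sklearn.metrics import silhouette_score
        assert silhouette_score(res.coords, data.labels) > 0.5

    def test_seeded_determinism(self):
        data = generate_clusters(10, 10, separation=5.0, seed=5)
        dist = similarity_to_distance(data.similarity)
        a = tsne(dist, perplexity=5, seed=42, max_iter=260)
        b = tsne(dist, perplexity=5, seed=42, max_iter=260)
        np.testing.assert_array_equal(a.coords, b.coords)
        c = tsne(dist, perplexity=5, seed=43, max_iter=260)
        assert not np.array_equal(a.coords, c.coords)

    def test_does_not_mutate_input(self):
        data = generate_clusters(8, 8, separation=5.0, seed=6)
        dist = similarity_to_distance(data.similarity)
        before = dist.values.copy()
        tsne(dist, perplexity=4, seed=0, max_iter=260)
        np.testing.assert_array_equal(before, dist.values)

    def test_perplexity_bound(self):
        dm = euclidean_dm(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValidationError, match="perplexity"):
            tsne(dm, perplexity=30)


class TestLocalityPreservation:
    def test_neighbourhoods_beat_random_projection(self):
        data = generate_clusters(30, 30, n_clusters=3, separation=6.0,
                                 noise_sd=1.0, seed=9)
        dist = similarity_to_distance(data.similarity)
        from scipy.spatial.distance import squareform

        def knn_overlap(d_a, d_b, k=5):
            overlaps = []
            for i in range(d_a.shape[0]):
                na = set(np.argsort(d_a[i])[1:k + 1])
                nb = set(np.argsort(d_b[i])[1:k + 1])
                overlaps.append(len(na & nb) / k)
            return float(np.mean(overlaps))

        latent_d = squareform(pdist(data.latent))
        rng = np.random.default_rng(0)
        random_coords = rng.normal(size=data.latent.shape)
        random_d = squareform(pdist(random_coords))
        baseline = knn_overlap(latent_d, random_d)
        for method in ("pcooa", "kmds", "sammon"):
            res = project(dist, method)
            proj_d = squareform(pdist(res.coords))
            assert knn_overlap(latent_d, proj_d) > baseline


class TestProjectDispatcher:
    def test_unknown_method(self, planar_cloud):
        _, dm = planar_cloud
        with pytest.raises(ValidationError, match="unknown projection"):
            project(dm, "umap")
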