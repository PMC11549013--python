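"""Star-convex geometry: rays, distance encoding, rasterization, NMS."""

import numpy as np
import pytest

from delicate.geometry import (PolyhedronSet, encode_distances, nms,
                               pairwise_overlap, rasterize, ray_directions)


def render_sphere(radius_vox: int, pad: int = 3) -> np.ndarray:
    n = 2 * (radius_vox + pad) + 1
    c = n // 2
    zz, yy, xx = np.mgrid[:n, :n, :n]
    lab = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2
           <= radius_vox ** 2).astype(np.int32)
    return lab


class TestRayDirections:
    def test_unit_norms(self):
        rays = ray_directions(64)
        assert len(rays) == 64
        norms = np.linalg.norm(rays.directions, axis=1)
        assert np.abs(norms - 1).max() < 1e-9

    def test_single_ray_points_up(self):
        rays = ray_directions(1)
        np.testing.assert_allclose(rays.directions, [[1.0, 0, 0]])

    def test_near_uniform_coverage(self):
        rays = ray_directions(64)
        assert np.linalg.norm(rays.directions.mean(axis=0)) < 0.05

    def test_rejects_zero_rays(self):
        with pytest.raises(ValueError):
            ray_directions(0)


class TestEncodeDistances:
    def test_sphere_center_distances(self):
        lab = render_sphere(8)
        rays = ray_directions(64)
        c = np.array([[lab.shape[0] // 2] * 3])
        _, dist = encode_distances(lab, rays, voxels=c)
        assert dist.shape == (1, 64)
        assert dist.min() >= 7 and dist.max() <= 9

    def test_cube_axis_and_diagonal(self):
        a = 6
        lab = np.zeros((21, 21, 21), np.int32)
        lab[10 - a:10 + a + 1, 10 - a:10 + a + 1, 10 - a:10 + a + 1] = 1
        rays = ray_directions(64)
        _, dist = encode_distances(lab, rays, voxels=np.array([[10, 10, 10]]))
        # closest rays to the +z axis and to the body diagonal
        axis_ray = np.argmax(rays.directions @ np.array([1.0, 0, 0]))
        diag = np.array([1.0, 1, 1]) / np.sqrt(3)
        diag_ray = np.argmax(rays.directions @ diag)
        assert abs(dist[0, axis_ray] - a) <= 1.0
        assert abs(dist[0, diag_ray] - a * np.sqrt(3)) <= 1.5

    def test_background_voxel_zero(self):
        lab = render_sphere(4)
        rays = ray_directions(8)
        obj, dist = encode_distances(lab, rays, voxels=np.array([[0, 0, 0]]))
        assert obj[0, 0, 0] == 0
        assert np.all(dist == 0)

    def test_objectness_is_foreground(self):
        lab = render_sphere(4)
        obj, _ = encode_distances(lab, ray_directions(4),
                                  voxels=np.zeros((0, 3), int))
        np.testing.assert_array_equal(obj, (lab > 0).astype(np.float32))


class TestRasterize:
    def test_constant_distances_give_a_ball(self):
        r = 8
        rays = ray_directions(64)
        polys = PolyhedronSet(np.array([[12.0, 12, 12]]),
                              np.full((1, 64), float(r)),
                              np.array([0.9]), rays)
        lab = rasterize(polys, (25, 25, 25))
        ball = render_sphere(r, pad=4)
        inter = np.logical_and(lab > 0, ball > 0).sum()
        union = np.logical_or(lab > 0, ball > 0).sum()
        assert inter / union >= 0.95

    def test_empty_set(self):
        lab = rasterize(PolyhedronSet.empty(), (8, 8, 8))
        assert lab.sum() == 0

    def test_contested_voxels_go_to_higher_score(self):
        rays = ray_directions(16)
        polys = PolyhedronSet(np.array([[8.0, 8, 8], [8.0, 8, 8]]),
                              np.full((2, 16), 4.0),
                              np.array([0.9, 0.8]), rays)
        lab = rasterize(polys, (17, 17, 17))
        assert set(np.unique(lab)) == {0, 1}  # label 1 = score 0.9

    def test_permutation_invariant(self):
        rng = np.random.default_rng(5)
        rays = ray_directions(16)
        centers = rng.uniform(5, 25, size=(5, 3))
        dists = np.full((5, 16), 4.0)
        scores = rng.uniform(0.1, 0.9, size=5)
        a = rasterize(PolyhedronSet(centers, dists, scores, rays), (30, 30, 30))
        p = rng.permutation(5)
        b = rasterize(PolyhedronSet(centers[p], dists[p], scores[p], rays),
                      (30, 30, 30))
        np.testing.assert_array_equal(a > 0, b > 0)
        # same spatial partition regardless of input order
        relabel = {}
        for la, lb in zip(a.ravel(), b.ravel()):
            relabel.setdefault(la, lb)
            assert relabel[la] == lb


class TestPairwiseOverlap:
    def test_identical_is_one(self):
        rays = ray_directions(32)
        c = np.array([10.0, 10, 10])
        dvec = np.full(32, 6.0)
        assert pairwise_overlap(c, dvec, c, dvec, rays) == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        rays = ray_directions(32)
        d1 = np.full(32, 3.0)
        assert pairwise_overlap([5, 5, 5], d1, [50, 50, 50], d1, rays) == 0.0

    def test_matches_lens_volume_formula(self):
        # equal spheres radius r, centres d apart:
        # V_lens = pi (4 r + d) (2 r - d)^2 / 12
        r, dist = 8.0, 8.0
        v_sphere = 4 / 3 * np.pi * r ** 3
        v_lens = np.pi * (4 * r + dist) * (2 * r - dist) ** 2 / 12
        expected = v_lens / (2 * v_sphere - v_lens)
        rays = ray_directions(64)
        dvec = np.full(64, r)
        got = pairwise_overlap([20.0, 20, 20], dvec, [20.0, 20, 28], dvec, rays)
        assert abs(got - expected) < 0.02


def brute_force_nms(centers, dists, scores, rays, thr):
    order = sorted(range(len(scores)),
                   key=lambda i: (-scores[i], tuple(centers[i])))
    accepted = []
    for i in order:
        if all(pairwise_overlap(centers[i], dists[i], centers[j], dists[j],
                                rays) < thr for j in accepted):
            accepted.append(i)
    return accepted


class TestNMS:
    def test_duplicate_suppressed(self):
        rays = ray_directions(16)
        polys = PolyhedronSet(np.array([[8.0, 8, 8], [8.0, 8, 8]]),
                              np.full((2, 16), 4.0),
                              np.array([0.9, 0.8]), rays)
        kept = nms(polys, 0.5)
        assert len(kept) == 1
        assert kept.scores[0] == pytest.approx(0.9)

    def test_disjoint_all_kept(self):
        rays = ray_directions(16)
        centers = np.array([[10.0, 10, 10], [10.0, 10, 40], [40.0, 10, 10]])
        polys = PolyhedronSet(centers, np.full((3, 16), 4.0),
                              np.array([0.5, 0.6, 0.7]), rays)
        for thr in (0.1, 0.5, 0.9):
            assert len(nms(polys, thr)) == 3

    def test_matches_brute_force_on_random_sets(self):
        # independent greedy reimplementation as the oracle
        rng = np.random.default_rng(11)
        rays = ray_directions(16)
        for _ in range(25):
            n = rng.integers(2, 12)
            centers = rng.uniform(4, 28, size=(n, 3))
            dists = np.tile(rng.uniform(2, 6, size=(n, 1)), (1, 16))
            scores = rng.uniform(0, 1, size=n)
            polys = PolyhedronSet(centers, dists, scores, rays)
            kept = nms(polys, 0.3)
            expect = brute_force_nms(centers, dists, scores, rays, 0.3)
            got = {tuple(c) for c in kept.centers}
            want = {tuple(centers[i]) for i in expect}
            assert got == want

    def test_antichain_property(self):
        rng = np.random.default_rng(3)
        rays = ray_directions(16)
        centers = rng.uniform(4, 20, size=(12, 3))
        dists = np.tile(rng.uniform(3, 6, size=(12, 1)), (1, 16))
        scores = rng.uniform(0, 1, size=12)
        polys = PolyhedronSet(centers, dists, scores, rays)
        kept = nms(polys, 0.3)
        k = len(kept)
        for i in range(k):
            for j in range(i + 1, k):
                iou = pairwise_overlap(kept.centers[i], kept.distances[i],
                                       kept.centers[j], kept.distances[j], rays)
                assert iou < 0.3
        # every rejected candidate overlaps some accepted one
        kept_set = {tuple(c) for c in kept.centers}
        for i in range(len(polys)):
            if tuple(centers[i]) in kept_set:
                continue
            assert any(pairwise_overlap(centers[i], dists[i], kept.centers[j],
                                        kept.distances[j], rays) >= 0.3
                       for j in range(k))


def test_polyhedron_set_json_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    rays = ray_directions(16)
    polys = PolyhedronSet(rng.uniform(0, 20, (3, 3)),
                          rng.uniform(1, 5, (3, 16)),
                          rng.uniform(0, 1, 3), rays)
    path = tmp_path / "polys.json"
    polys.to_json(path)
    back = PolyhedronSet.from_json(path)
    np.testing.assert_allclose(back.centers, polys.centers)
    np.testing.assert_allclose(back.distances, polys.distances)
    np.testing.assert_allclose(back.scores, polys.scores)
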