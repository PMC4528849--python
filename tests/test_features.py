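"""Surface feature histograms: normals, angular features, binning, weighting."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from phenoseg.features import (
    DegeneratePairError,
    EmptyHistogramError,
    FeatureParams,
    bin_index,
    compute_histograms,
    estimate_normals,
    feature_triple,
    read_histograms,
    single_point_histogram,
    weighted_histograms,
    write_histograms,
)
from phenoseg.io import PointCloud
from phenoseg.scenes import PrimitiveSpec, generate_scene, sample_primitive
from phenoseg.simplex import aitchison_distance, replace_zeros

PLANE_BIN = 62  # all three features at the center of their domain, b=5


class TestFeatureParams:
    def test_radius_ordering_enforced(self):
        with pytest.raises(ValueError):
            FeatureParams(r_normal=12.5, r_hist=2.5)

    def test_histogram_length_is_bins_cubed(self):
        assert FeatureParams(bins=5).n_bins == 125
        assert FeatureParams(bins=3).n_bins == 27


class TestNormals:
    def test_plane_normals_point_up(self, plane_cloud):
        nf = estimate_normals(plane_cloud)
        assert nf.valid.all()
        assert np.allclose(np.abs(nf.normals[:, 2]), 1.0, atol=1e-9)
        assert np.allclose(np.linalg.norm(nf.normals, axis=1), 1.0, atol=1e-9)

    def test_cylinder_normal_is_radial(self, cylinder_cloud):
        nf = estimate_normals(cylinder_cloud)
        i = np.argmin(np.linalg.norm(cylinder_cloud.points - [5, 0, 15], axis=1))
        assert abs(abs(nf.normals[i, 0]) - 1.0) < 1e-2
        # outward orientation: radially aligned with the point position
        radial = cylinder_cloud.points[i] * [1, 1, 0]
        radial /= np.linalg.norm(radial)
        assert np.dot(nf.normals[i], radial) > 0.99

    def test_isolated_points_flagged_invalid(self):
        pc = PointCloud([[0, 0, 0], [10, 0, 0]])
        nf = estimate_normals(pc, FeatureParams(r_normal=2.5, r_hist=12.5))
        assert not nf.valid.any()

    def test_plane_interior_normals_within_one_degree(self):
        """sigma=0 and spacing <= r_normal/3: >=99% within 1 degree of analytic."""
        pc = sample_primitive(
            PrimitiveSpec("plane_patch", 1, length=20, width=20), 0.5, 0.0, 0
        )
        nf = estimate_normals(pc, FeatureParams(r_normal=2.5, r_hist=12.5))
        interior = np.all((pc.points[:, :2] > 2.5) & (pc.points[:, :2] < 17.5), axis=1)
        ang = np.degrees(np.arccos(np.clip(np.abs(nf.normals[interior, 2]), -1, 1)))
        assert (ang < 1.0).mean() >= 0.99


class TestFeatureTriple:
    def test_coplanar_pair_is_origin_of_feature_space(self):
        t = feature_triple([0, 0, 0], [0, 0, 1], [1, 0, 0], [0, 0, 1])
        assert t == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    def test_unit_cylinder_pair(self):
        t = feature_triple([1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 1, 0])
        assert t == pytest.approx((0.0, -np.sqrt(0.5), np.pi / 2), abs=1e-4)

    def test_antipodal_normals_on_plane(self):
        t = feature_triple([0, 0, 0], [0, 0, 1], [1, 0, 0], [0, 0, -1])
        assert t[0] == pytest.approx(0.0, abs=1e-12)
        assert abs(t[2]) == pytest.approx(np.pi, abs=1e-12)

    def test_degenerate_displacement_parallel_to_normal(self):
        with pytest.raises(DegeneratePairError):
            feature_triple([0, 0, 0], [0, 0, 1], [0, 0, 2], [0, 0, 1])

    def test_components_within_domain(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            z_i, z_j = rng.normal(size=(2, 3))
            n_i, n_j = rng.normal(size=(2, 3))
            n_i /= np.linalg.norm(n_i)
            n_j /= np.linalg.norm(n_j)
            try:
                t0, t1, t2 = feature_triple(z_i, n_i, z_j, n_j)
            except DegeneratePairError:
                continue
            assert -1 <= t0 <= 1 and -1 <= t1 <= 1 and -np.pi <= t2 <= np.pi


class TestBinIndex:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((0.0, 0.0, 0.0), 62),          # center of every domain -> (2,2,2)
            ((-1.0, -1.0, -np.pi), 0),      # all minima
            ((1.0, 1.0, np.pi), 124),       # maxima clamp to top subregion
        ],
    )
    def test_frozen_examples(self, triple, expected):
        assert bin_index(triple, 5) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_index((1.5, 0.0, 0.0), 5)

    def test_surjective_and_in_bounds(self):
        """Every bin in [0, b^3) is reachable; none is ever exceeded."""
        b = 4
        rng = np.random.default_rng(1)
        seen = set()
        for _ in range(5000):
            t = (rng.uniform(-1, 1), rng.uniform(-1, 1), rng.uniform(-np.pi, np.pi))
            idx = bin_index(t, b)
            assert 0 <= idx < b**3
            seen.add(idx)
        assert seen == set(range(b**3))


class TestSinglePointHistograms:
    def test_plane_concentrates_in_one_bin(self, plane_cloud):
        nf = estimate_normals(plane_cloud)
        h = single_point_histogram(plane_cloud, nf, 220)
        assert h.sum() == h[PLANE_BIN]

    def test_count_conservation(self, plane_cloud):
        params = FeatureParams()
        nf = estimate_normals(plane_cloud, params)
        i = 220
        d = np.linalg.norm(plane_cloud.points - plane_cloud.points[i], axis=1)
        usable = ((d <= params.r_hist) & nf.valid).sum() - 1  # minus self
        h = single_point_histogram(plane_cloud, nf, i, params)
        assert h.sum() == usable  # plane has no degenerate pairs

    def test_isolated_point_raises(self):
        pc = PointCloud(np.vstack([np.eye(3) * 0.2, [[100, 100, 100]]]))
        nf = estimate_normals(pc, FeatureParams(r_normal=2.5, r_hist=12.5))
        with pytest.raises(EmptyHistogramError):
            single_point_histogram(pc, nf, 3)

    def test_batch_matches_scalar_reference(self, small_noisy_scene):
        """Vectorized pair binning agrees with the loop over feature_triple."""
        from phenoseg.features import _all_single_point_histograms
        from scipy.spatial import cKDTree

        _, pc = small_noisy_scene
        sub = PointCloud(pc.points[::13], labels=None)
        params = FeatureParams()
        nf = estimate_normals(sub, params)
        pairs = cKDTree(sub.points).query_pairs(params.r_hist, output_type="ndarray")
        batch = _all_single_point_histograms(sub.points, nf, params, pairs)
        for i in np.flatnonzero(nf.valid)[:10]:
            assert np.array_equal(batch[i], single_point_histogram(sub, nf, i, params))


class TestWeightedHistograms:
    def test_beta_endpoints(self):
        # beta = 0.5 * (1 - d / r_hist): 0.5 at d=0, 0 at the rim
        r_hist = 12.5
        beta = lambda d: 0.5 * (1 - d / r_hist)
        assert beta(0.0) == 0.5
        assert beta(r_hist) == 0.0

    def test_plane_rows_are_indicator_of_plane_bin(self, plane_histograms):
        H = plane_histograms.histograms
        assert np.allclose(H[:, PLANE_BIN], 1.0)
        assert np.allclose(H.sum(axis=1), 1.0, atol=1e-9)

    def test_rows_normalized_nonnegative(self, small_noisy_scene):
        _, pc = small_noisy_scene
        hs = compute_histograms(pc)
        assert np.all(hs.histograms >= 0)
        assert np.allclose(hs.histograms.sum(axis=1), 1.0, atol=1e-9)

    def test_all_dropped_raises(self):
        pc = PointCloud(np.diag([100.0, 200.0, 300.0]))
        nf = estimate_normals(pc)
        with pytest.raises(EmptyHistogramError):
            weighted_histograms(pc, nf)


class TestComputeHistograms:
    def test_default_params_give_125_bins(self, plane_histograms):
        assert plane_histograms.histograms.shape[1] == 125
        assert plane_histograms.params.bins == 5

    def test_plane_and_cylinder_mean_histograms_differ(
        self, plane_histograms, cylinder_histograms
    ):
        mp = replace_zeros(plane_histograms.histograms.mean(axis=0))
        mc = replace_zeros(cylinder_histograms.histograms.mean(axis=0))
        assert aitchison_distance(mp, mc) > 0.5

    def test_order_equivariance(self, plane_cloud):
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(plane_cloud))
        hs1 = compute_histograms(plane_cloud)
        hs2 = compute_histograms(PointCloud(plane_cloud.points[perm]))
        # map rows back to original point ids and compare
        back = np.empty(len(plane_cloud), dtype=int)
        back[perm] = np.arange(len(plane_cloud))
        orig_of_row2 = perm[hs2.point_index_map]
        order = np.argsort(orig_of_row2)
        assert np.array_equal(hs1.point_index_map, orig_of_row2[order])
        assert np.allclose(hs1.histograms, hs2.histograms[order], atol=1e-9)

    def test_rigid_motion_invariance(self, small_noisy_scene):
        """Features are relative: a rotated+translated cloud gives the same
        histograms to within numerical round-off."""
        _, pc = small_noisy_scene
        hs1 = compute_histograms(pc)
        rng = np.random.default_rng(7)
        R = Rotation.random(rng=rng)
        moved = PointCloud(R.apply(pc.points) + rng.uniform(-50, 50, 3))
        hs2 = compute_histograms(moved)
        assert np.array_equal(hs1.point_index_map, hs2.point_index_map)
        assert np.abs(hs1.histograms - hs2.histograms).max() <= 1e-6


class TestHistogramIO:
    def test_round_trip(self, tmp_path, plane_histograms):
        path = tmp_path / "hist.tsv"
        write_histograms(plane_histograms, path)
        back = read_histograms(path)
        assert np.array_equal(back.point_index_map, plane_histograms.point_index_map)
        assert np.allclose(back.histograms, plane_histograms.histograms, atol=1e-9)
        assert back.params.bins == 5
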