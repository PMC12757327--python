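import numpy as np
import pytest

import mrcomplete as mc
from mrcomplete.core_geometry import CloudParseError


class TestIO:
    def test_xyz_file_order_preserved(self, tmp_path):
        path = tmp_path / "tri.xyz"
        path.write_text("0 0 0\n1 0 0\n0 1 0\n")
        cloud = mc.read_cloud(str(path))
        assert np.array_equal(
            cloud.points, [[0, 0, 0], [1, 0, 0], [0, 1, 0]]
        )

    def test_xyz_comments_and_blank_lines_ignored(self, tmp_path):
        path = tmp_path / "c.xyz"
        path.write_text("# header\n\n1 2 3  # trailing\n")
        assert len(mc.read_cloud(str(path))) == 1

    def test_xyz_round_trip_is_identity(self, tmp_path, rng):
        cloud = mc.PointCloud(rng.normal(size=(50, 3)))
        p1, p2 = tmp_path / "a.xyz", tmp_path / "b.xyz"
        mc.write_cloud(cloud, str(p1))
        once = mc.read_cloud(str(p1))
        # 9 significant digits survive one trip ...
        np.testing.assert_allclose(once.points, cloud.points, rtol=1e-8)
        # ... and the second trip is bit-exact
        mc.write_cloud(once, str(p2))
        twice = mc.read_cloud(str(p2))
        assert np.array_equal(once.points, twice.points)

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("0 0 0\n1 2\n")
        with pytest.raises(CloudParseError, match=":2:"):
            mc.read_cloud(str(path))

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.xyz"
        path.write_text("# only a comment\n")
        with pytest.raises(CloudParseError):
            mc.read_cloud(str(path))

    def test_ply_ascii_round_trip(self, tmp_path, rng):
        cloud = mc.PointCloud(rng.normal(size=(2048, 3)))
        path = tmp_path / "cloud.ply"
        mc.write_cloud(cloud, str(path))
        back = mc.read_cloud(str(path))
        assert len(back) == 2048
        np.testing.assert_allclose(back.points, cloud.points, rtol=1e-6)

    def test_ply_binary_read(self, tmp_path, rng):
        import trimesh

        pts = rng.normal(size=(100, 3))
        path = tmp_path / "bin.ply"
        trimesh.PointCloud(pts).export(str(path))  # binary little-endian
        back = mc.read_cloud(str(path))
        assert len(back) == 100
        np.testing.assert_allclose(back.points, pts, atol=1e-6)


class TestPointCloudInvariants:
    def test_rejects_nan(self):
        with pytest.raises(ValueError):
            mc.PointCloud(np.array([[0.0, np.nan, 0.0]]))

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            mc.PointCloud(np.empty((0, 3)))

    def test_duplicates_permitted(self):
        cloud = mc.PointCloud([[1, 2, 3], [1, 2, 3]])
        assert len(cloud) == 2


class TestCenter:
    def test_bounding_box_midpoint_subtracted(self):
        out = mc.center(mc.PointCloud([[2, 0, 0], [4, 0, 0]]))
        np.testing.assert_allclose(out.points, [[-1, 0, 0], [1, 0, 0]])

    def test_per_axis_midpoint(self):
        out = mc.center(mc.PointCloud([[0, 0, 0], [0, 6, 0], [0, 0, 2]]))
        np.testing.assert_allclose(
            out.points, [[0, -3, -1], [0, 3, -1], [0, -3, 1]]
        )

    def test_symmetric_cloud_unchanged(self):
        pts = np.array([[1.0, -2.0, 0.5], [-1.0, 2.0, -0.5]])
        np.testing.assert_allclose(mc.center(mc.PointCloud(pts)).points, pts)

    def test_idempotent(self, rng):
        cloud = mc.PointCloud(rng.normal(size=(40, 3)) + 5.0)
        once = mc.center(cloud)
        twice = mc.center(once)
        np.testing.assert_allclose(once.points, twice.points, atol=1e-12)
        mid = once.points.min(0) + (once.points.max(0) - once.points.min(0)) / 2
        np.testing.assert_allclose(mid, 0.0, atol=1e-9)

    def test_uses_box_midpoint_not_centroid(self):
        # dense cluster at one end shifts the centroid but not the midpoint
        pts = np.vstack([np.zeros((9, 3)), [[4.0, 0.0, 0.0]]])
        out = mc.center(mc.PointCloud(pts))
        assert out.points[:, 0].max() == pytest.approx(2.0)


class TestNormalize:
    def test_divides_by_longest_half_extent(self):
        cloud = mc.PointCloud([[-5.0, 1.0, 0.0], [5.0, -1.0, 0.0]])
        out = mc.normalize(cloud)
        np.testing.assert_allclose(
            out.points, [[-1.0, 0.2, 0.0], [1.0, -0.2, 0.0]]
        )

    def test_unit_cloud_unchanged(self):
        pts = np.array([[-1.0, 0.3, 0.0], [1.0, -0.3, 0.0]])
        np.testing.assert_allclose(mc.normalize(mc.PointCloud(pts)).points, pts)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_bounded_by_one_touching_longest_axis(self, seed):
        rng = np.random.default_rng(seed)
        cloud = mc.center(mc.PointCloud(rng.normal(size=(100, 3)) * [3, 1, 0.5]))
        out = mc.normalize(cloud)
        assert np.abs(out.points).max() <= 1.0 + 1e-12
        extent = out.points.max(0) - out.points.min(0)
        assert extent.max() == pytest.approx(2.0)

    def test_degenerate_cloud_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            mc.normalize(mc.PointCloud([[0, 0, 0], [0, 0, 0]]))

    def test_uncentered_cloud_rejected(self):
        with pytest.raises(ValueError, match="centered"):
            mc.normalize(mc.PointCloud([[0, 0, 0], [10, 0, 0]]))


class TestRotation:
    def test_zero_angles_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        out = mc.random_rotation_augment(mc.PointCloud(pts), 0, angles=(0, 0, 0))
        np.testing.assert_allclose(out.points, pts)

    def test_quarter_turn_about_z(self):
        out = mc.random_rotation_augment(
            mc.PointCloud([[1.0, 0.0, 0.0]]), 0, angles=(0, 0, np.pi / 2)
        )
        np.testing.assert_allclose(out.points, [[0, 1, 0]], atol=1e-12)

    def test_seeded_determinism(self, rng):
        cloud = mc.PointCloud(rng.normal(size=(20, 3)))
        a = mc.random_rotation_augment(cloud, 7)
        b = mc.random_rotation_augment(cloud, 7)
        assert np.array_equal(a.points, b.points)

    def test_rigid_motion_properties(self, rng):
        from scipy.spatial.distance import pdist
        from mrcomplete.core_geometry import rotation_from_angles

        cloud = mc.PointCloud(rng.normal(size=(30, 3)))
        out = mc.random_rotation_augment(cloud, 3)
        np.testing.assert_allclose(
            pdist(out.points), pdist(cloud.points), atol=1e-9
        )
        np.testing.assert_allclose(
            np.linalg.norm(out.points.mean(0)),
            np.linalg.norm(cloud.points.mean(0)),
            atol=1e-9,
        )
        rot = rotation_from_angles(np.random.default_rng(3).uniform(0, 2 * np.pi, 3))
        assert np.linalg.det(rot) == pytest.approx(1.0)


class TestSplit:
    def test_60_20_20_on_1000(self):
        split = mc.split_dataset(range(1000), seed=0)
        assert (len(split.train), len(split.val), len(split.test)) == (600, 200, 200)

    def test_remainder_goes_to_test(self):
        split = mc.split_dataset(range(5), seed=0)
        assert (len(split.train), len(split.val), len(split.test)) == (3, 1, 1)

    def test_partition_disjoint_and_exhaustive(self):
        ids = [f"c{i}" for i in range(37)]
        split = mc.split_dataset(ids, seed=5)
        union = set(split.train) | set(split.val) | set(split.test)
        assert union == set(ids)
        assert len(split.train) + len(split.val) + len(split.test) == 37

    def test_seed_reproducible(self):
        a = mc.split_dataset(range(50), seed=9)
        b = mc.split_dataset(range(50), seed=9)
        assert a.train == b.train and a.val == b.val and a.test == b.test

    def test_too_few_ids_rejected(self):
        with pytest.raises(ValueError):
            mc.split_dataset(range(4), seed=0)
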