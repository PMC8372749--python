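"""Volume / point-set I/O and the burn-extract round trip."""

import numpy as np
import pytest

from mmii import (BurnSettings, FormatError, ImageVolume, Point, PointSet,
                  RigidTransform, ValidationError, burn_lines, burn_points,
                  extract_bright_points, plan_trajectory, read_pointset,
                  read_volume, write_pointset, write_volume)


def random_volume(rng, shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0)):
    aff = np.diag(list(spacing) + [1.0])
    return ImageVolume(rng.random(shape) * 100.0, aff, "other")


# ---------------------------------------------------------------------------
# read/write
# ---------------------------------------------------------------------------

class TestVolumeIO:
    def test_nifti_identity_affine(self, tmp_path, rng):
        vol = ImageVolume(rng.random((32, 32, 32)), np.eye(4))
        write_volume(vol, tmp_path / "v.nii.gz")
        back = read_volume(tmp_path / "v.nii.gz")
        assert back.shape == (32, 32, 32)
        np.testing.assert_allclose(back.voxel_size, [1, 1, 1])
        np.testing.assert_allclose(back.data, vol.data, atol=1e-5)

    def test_dicom_series_round_trip(self, tmp_path, rng):
        vol = random_volume(rng, (16, 12, 5), spacing=(1.0, 1.0, 2.0))
        write_volume(vol, tmp_path / "series", format="dicom_series")
        back = read_volume(tmp_path / "series")
        # slice direction: third affine column has the 2 mm slice step
        assert np.linalg.norm(back.affine[:3, 2]) == pytest.approx(2.0)
        assert np.abs(back.affine - vol.affine).max() < 1e-3
        assert np.abs(back.data - vol.data).max() < 0.01  # uint16 rounding

    def test_unreadable_input_names_file(self, tmp_path):
        bad = tmp_path / "notes.txt"
        bad.write_text("not an image")
        with pytest.raises(FormatError):
            read_volume(bad)

    def test_mixed_series_rejected(self, tmp_path, rng):
        write_volume(random_volume(rng, (8, 8, 2)), tmp_path / "d",
                     format="dicom_series")
        write_volume(random_volume(rng, (8, 8, 2)), tmp_path / "d2",
                     format="dicom_series")
        (tmp_path / "d" / "alien.dcm").write_bytes(
            (tmp_path / "d2" / "slice0000.dcm").read_bytes())
        with pytest.raises(FormatError, match="mixed|tied"):
            read_volume(tmp_path / "d")

    def test_empty_dims_rejected(self):
        with pytest.raises(ValidationError):
            ImageVolume(np.zeros((0, 4, 4)), np.eye(4))


# ---------------------------------------------------------------------------
# burn / extract
# ---------------------------------------------------------------------------

class TestBurnExtract:
    def test_empty_pointset_is_identity(self, rng):
        vol = random_volume(rng)
        out = burn_points(vol, PointSet([]))
        np.testing.assert_array_equal(out.data, vol.data)

    def test_single_point_becomes_argmax(self, rng):
        vol = random_volume(rng)
        out = burn_points(vol, PointSet([Point("a", 8, 8, 8)]),
                          BurnSettings(marker_radius=0.9))
        assert np.unravel_index(np.argmax(out.data), out.shape) == (8, 8, 8)

    def test_burn_only_touches_spheres(self, rng):
        vol = random_volume(rng, (24, 24, 24))
        s = BurnSettings(marker_radius=2.0)
        pts = PointSet([Point("a", 6, 6, 6), Point("b", 16, 16, 16)])
        out = burn_points(vol, pts, s)
        changed = np.argwhere(out.data != vol.data)
        world = vol.voxel_to_world(changed.astype(float))
        dist = np.minimum(
            np.linalg.norm(world - np.array([6., 6., 6.]), axis=1),
            np.linalg.norm(world - np.array([16., 16., 16.]), axis=1))
        assert (dist <= s.marker_radius).all()

    def test_out_of_fov_point_warned_and_skipped(self, rng):
        vol = random_volume(rng)
        with pytest.warns(UserWarning, match="outside"):
            out = burn_points(vol, PointSet([Point("far", 500, 0, 0)]))
        np.testing.assert_array_equal(out.data, vol.data)

    def test_round_trip_recovers_random_points(self, rng):
        """Burned points re-segment to within half a voxel."""
        vol = random_volume(rng, (40, 40, 40))
        s = BurnSettings(marker_radius=2.0, marker_intensity=1.5)
        for _ in range(5):  # property over random draws, seeded
            while True:
                pts = rng.uniform(6, 34, size=(5, 3))
                d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
                if d[np.triu_indices(5, 1)].min() > 2 * s.marker_radius + 1:
                    break
            ps = PointSet([Point(f"p{i}", *p) for i, p in enumerate(pts)])
            out = burn_points(vol, ps, s)
            got = extract_bright_points(out, 1.2 * float(vol.data.max()))
            assert len(got) == 5
            d = np.linalg.norm(got.coords[:, None] - pts[None], axis=2)
            assert d.min(axis=0).max() < 0.5  # 1 mm voxels

    def test_extract_empty_and_vacuous(self):
        vol = ImageVolume(np.zeros((8, 8, 8)), np.eye(4))
        assert len(extract_bright_points(vol, 0.5)) == 0
        vol2 = ImageVolume(np.ones((8, 8, 8)), np.eye(4))
        assert len(extract_bright_points(vol2, 2.0)) == 0

    def test_two_spheres_distance_preserved(self, rng):
        vol = ImageVolume(np.ones((40, 40, 40)), np.eye(4))
        ps = PointSet([Point("a", 10, 20, 20), Point("b", 30, 20, 20)])
        out = burn_points(vol, ps, BurnSettings(marker_radius=2.0))
        got = extract_bright_points(out, 1.1)
        assert len(got) == 2
        d = np.linalg.norm(got.coords[0] - got.coords[1])
        assert d == pytest.approx(20.0, abs=np.sqrt(3))


class TestBurnLines:
    def test_zero_trajectories_identity(self, rng):
        vol = random_volume(rng)
        out = burn_lines(vol, [])
        np.testing.assert_array_equal(out.data, vol.data)

    def test_axis_aligned_segment_voxel_count(self):
        """A 30 mm segment with sub-voxel radius burns one voxel per mm."""
        vol = ImageVolume(np.ones((40, 40, 40)), np.eye(4))
        t = plan_trajectory("T", (5, 20, 20), (35, 20, 20))
        out = burn_lines(vol, [t], BurnSettings(line_radius=0.4))
        n = int((out.data > 1).sum())
        assert abs(n - 31) <= 1

    def test_affine_survives_write_read(self, tmp_path, rng):
        vol = random_volume(rng)
        t = plan_trajectory("T", (2, 8, 8), (14, 8, 8))
        out = burn_lines(vol, [t])
        write_volume(out, tmp_path / "burned.nii.gz")
        back = read_volume(tmp_path / "burned.nii.gz")
        np.testing.assert_allclose(back.affine, vol.affine, atol=1e-6)


# ---------------------------------------------------------------------------
# point sets
# ---------------------------------------------------------------------------

class TestPointSetIO:
    def test_tsv_parse(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("name\tx\ty\tz\nA\t1\t2\t3\nB\t4\t5\t6\nC\t7\t8\t9\n")
        ps = read_pointset(p)
        assert ps.names == ["A", "B", "C"]
        np.testing.assert_allclose(ps["B"].xyz, [4, 5, 6])

    @pytest.mark.parametrize("ext", ["tsv", "json"])
    def test_round_trip_preserves_fields(self, tmp_path, ext):
        ps = PointSet([Point("A1", 1.5, -2.25, 3.0, "LA", 42.0),
                       Point("A2", 0.0, 0.5, -9.75, "LA", None)])
        path = tmp_path / f"p.{ext}"
        write_pointset(ps, path)
        back = read_pointset(path)
        assert back.names == ps.names
        np.testing.assert_allclose(back.coords, ps.coords)
        assert back["A1"].group == "LA"
        assert back["A1"].value == 42.0
        assert back["A2"].value is None

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("name\tx\ty\tz\nA1\t1\t2\t3\nA1\t4\t5\t6\n")
        with pytest.raises(ValidationError, match="A1"):
            read_pointset(p)


class TestRigidTransform:
    def test_rotation_block_validated(self):
        m = np.eye(4)
        m[0, 0] = 2.0
        with pytest.raises(ValidationError):
            RigidTransform(m)

    def test_compose_inverse_is_identity(self, rng):
        t = RigidTransform.from_params(*rng.uniform(-10, 10, 6))
        np.testing.assert_allclose(
            t.compose(t.inverse()).matrix, np.eye(4), atol=1e-9)

    def test_save_load_round_trip(self, tmp_path):
        t = RigidTransform.from_params(3, -4, 5, 1, 2, -3)
        for name in ("t.json", "t.txt"):
            t.save(tmp_path / name)
            np.testing.assert_allclose(
                RigidTransform.load(tmp_path / name).matrix, t.matrix,
                atol=1e-9)
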