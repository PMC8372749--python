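"""Resection mask voxelization, voxel mesh, containment and burn export."""

import numpy as np
import pytest

from mmii import (BurnSettings, ImageVolume, Point, PointSet,
                  export_burned_mask, markers_to_mask, mask_contains,
                  mask_to_voxel_mesh)
from mmii.resection import ResectionMask, write_obj


@pytest.fixture()
def base():
    rng = np.random.default_rng(0)
    aff = np.eye(4)
    aff[:3, 3] = -16.0
    return ImageVolume(rng.random((32, 32, 32)) * 100, aff, "t1", "base")


class TestMarkersToMask:
    def test_no_markers_empty_mask(self, base):
        rm = markers_to_mask(PointSet([]), 2.0, base)
        assert rm.voxel_count == 0

    def test_single_marker_sphere_volume(self, base):
        rm = markers_to_mask(PointSet([Point("m", 0, 0, 0)]), 5.0, base,
                             closing=False)
        vol = rm.voxel_count * float(np.prod(base.voxel_size))
        analytic = 4 / 3 * np.pi * 5 ** 3
        assert abs(vol - analytic) / analytic < 0.10

    def test_mask_local_to_markers(self, base):
        markers = PointSet([Point("a", -5, 0, 0, "s1"),
                            Point("b", 5, 0, 0, "s1")])
        rm = markers_to_mask(markers, 2.0, base)
        world = base.voxel_to_world(np.argwhere(rm.mask).astype(float))
        # bounding box of markers dilated by brush + closing radius
        pad = 2.0 + 1.0 + float(np.sqrt(3)) / 2
        assert (world >= [-5 - pad, -pad, -pad]).all()
        assert (world <= [5 + pad, pad, pad]).all()

    def test_stroke_connects_consecutive_markers(self, base):
        from scipy import ndimage
        markers = PointSet([Point("a", -8, 0, 0, "s1"),
                            Point("b", 8, 0, 0, "s1")])
        rm = markers_to_mask(markers, 2.0, base)
        _, n = ndimage.label(rm.mask)
        assert n == 1  # swept capsule joins the two spheres

    def test_monotone_in_brush_radius(self, base):
        markers = PointSet([Point("a", 0, 0, 0), Point("b", 6, 2, -3)])
        small = markers_to_mask(markers, 2.0, base).mask
        big = markers_to_mask(markers, 4.0, base).mask
        assert (big | small == big).all()


class TestVoxelMesh:
    def test_single_voxel_six_faces(self):
        rm = ResectionMask(np.zeros((4, 4, 4), bool), np.eye(4), 1.0,
                           PointSet([Point("m", 1, 1, 1)]))
        rm.mask[1, 1, 1] = True
        verts, faces = mask_to_voxel_mesh(rm)
        assert len(faces) == 6
        assert len(verts) == 8

    def test_2x2x2_block_24_faces(self):
        rm = ResectionMask(np.zeros((5, 5, 5), bool), np.eye(4), 1.0,
                           PointSet([Point("m", 1, 1, 1)]))
        rm.mask[1:3, 1:3, 1:3] = True
        _, faces = mask_to_voxel_mesh(rm)
        assert len(faces) == 24

    def test_face_count_matches_brute_force(self, rng):
        mask = rng.random((10, 10, 10)) > 0.6
        rm = ResectionMask(mask, np.eye(4), 1.0,
                           PointSet([Point("m", 1, 1, 1)]))
        _, faces = mask_to_voxel_mesh(rm)
        # brute force: count exposed faces voxel by voxel
        count = 0
        for v in np.argwhere(mask):
            for ax in range(3):
                for side in (-1, 1):
                    nb = v.copy()
                    nb[ax] += side
                    if (nb < 0).any() or (nb >= 10).any() or \
                            not mask[tuple(nb)]:
                        count += 1
        assert len(faces) == count

    def test_solid_mask_mesh_closed(self, base):
        rm = markers_to_mask(PointSet([Point("m", 0, 0, 0)]), 5.0, base)
        _, faces = mask_to_voxel_mesh(rm)
        edges = {}
        for q in faces:
            for i in range(4):
                e = tuple(sorted((q[i], q[(i + 1) % 4])))
                edges[e] = edges.get(e, 0) + 1
        assert set(edges.values()) == {2}

    def test_obj_export(self, tmp_path):
        rm = ResectionMask(np.zeros((3, 3, 3), bool), np.eye(4), 1.0,
                           PointSet([Point("m", 1, 1, 1)]))
        rm.mask[1, 1, 1] = True
        verts, faces = mask_to_voxel_mesh(rm)
        write_obj(verts, faces, tmp_path / "m.obj")
        lines = (tmp_path / "m.obj").read_text().splitlines()
        assert sum(l.startswith("v ") for l in lines) == 8
        assert sum(l.startswith("f ") for l in lines) == 6


class TestContainmentAndBurn:
    def test_marker_center_inside(self, base):
        markers = PointSet([Point("m", 0, 0, 0)])
        rm = markers_to_mask(markers, 3.0, base)
        table = mask_contains(rm, markers)
        assert table.loc[0, "inside"]

    def test_far_point_outside(self, base):
        rm = markers_to_mask(PointSet([Point("m", 0, 0, 0)]), 3.0, base)
        table = mask_contains(rm, PointSet([Point("far", 100, 100, 100)]))
        assert not table.loc[0, "inside"]

    def test_containment_matches_analytic_spheres(self, base, rng):
        """Without closing, inside/outside equals distance-to-marker
        comparison against the brush radius (up to voxel quantization)."""
        centers = rng.uniform(-8, 8, size=(3, 3))
        markers = PointSet([Point(f"m{i}", *c, f"g{i}")
                            for i, c in enumerate(centers)])
        rm = markers_to_mask(markers, 4.0, base, closing=False)
        probes = PointSet([Point(f"p{i}", *rng.uniform(-12, 12, 3))
                           for i in range(40)])
        table = mask_contains(rm, probes)
        for _, row in table.iterrows():
            p = np.array([row.x, row.y, row.z])
            # analytic distance evaluated at the probe's voxel centre
            vc = base.voxel_to_world(
                np.round(base.world_to_voxel(p))).ravel()
            d = np.linalg.norm(centers - vc, axis=1).min()
            assert row.inside == (d <= 4.0)

    def test_empty_mask_burn_is_identity(self, base):
        rm = markers_to_mask(PointSet([]), 2.0, base)
        out = export_burned_mask(base, rm)
        np.testing.assert_array_equal(out.data, base.data)

    def test_burned_voxels_exceed_global_max(self, base):
        rm = markers_to_mask(PointSet([Point("m", 0, 0, 0)]), 4.0, base)
        out = export_burned_mask(base, rm, BurnSettings())
        assert (out.data[rm.mask] > base.data.max()).all()

    def test_burn_threshold_round_trip_dice(self, base, rng):
        for _ in range(10):
            pts = rng.uniform(-10, 10, size=(4, 3))
            markers = PointSet([Point(f"m{i}", *p, "s")
                                for i, p in enumerate(pts)])
            rm = markers_to_mask(markers, 3.0, base)
            burned = export_burned_mask(base, rm, BurnSettings())
            recovered = burned.data > base.data.max()
            inter = (recovered & rm.mask).sum()
            dice = 2 * inter / (recovered.sum() + rm.mask.sum())
            assert dice >= 0.99
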