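"""Talairach proportional grid: frame construction, cell assignment,
dividing planes, and rigid equivariance."""

import numpy as np
import pytest

from mmii import (BrainBounds, GeometryError, RigidTransform,
                  ValidationError, build_frame, cell_center, grid_cell,
                  grid_planes)

BOUNDS = dict(anterior=70, posterior=80, superior=70, inferior=45,
              left=65, right=65)


@pytest.fixture()
def frame():
    return build_frame((0, 0, 0), (0, -23, 0), (0, 0, 40),
                       BrainBounds(**BOUNDS))


class TestBuildFrame:
    def test_axis_aligned_construction(self, frame):
        np.testing.assert_allclose(frame.axes, np.eye(3), atol=1e-12)
        # VCA is the plane y=0, VCP the plane y=-23 (frame coords = world)
        assert grid_cell((0, 0.01, 5), frame).sector == "D"
        assert grid_cell((0, -0.01, 5), frame).sector == "E"
        assert grid_cell((0, -22.99, 5), frame).sector == "E"
        assert grid_cell((0, -23.01, 5), frame).sector == "F"

    def test_collinear_ms_rejected(self):
        with pytest.raises(GeometryError):
            build_frame((0, 0, 0), (0, -23, 0), (0, 10, 0),
                        BrainBounds(**BOUNDS))

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValidationError):
            build_frame((0, 0, 0), (0, -23, 0), (0, 0, 40),
                        BrainBounds(**{**BOUNDS, "posterior": 20}))

    def test_rigid_equivariance(self, frame, rng):
        """Transforming the landmarks transforms the frame: grid cells of
        transformed points are unchanged."""
        pts = rng.uniform(-1, 1, size=(30, 3)) * [60, 60, 40]
        for _ in range(5):
            t = RigidTransform.from_params(*(rng.uniform(-1, 1, 6)
                                             * [30, 30, 30, 20, 20, 20]))
            tf = build_frame(t.apply((0, 0, 0))[0], t.apply((0, -23, 0))[0],
                             t.apply((0, 0, 40))[0], BrainBounds(**BOUNDS))
            for p in pts:
                c0 = grid_cell(p, frame)
                c1 = grid_cell(t.apply(p)[0], tf)
                assert (c0.sector, c0.level, c0.column, c0.hemisphere,
                        c0.in_grid) == \
                       (c1.sector, c1.level, c1.column, c1.hemisphere,
                        c1.in_grid)

    def test_frame_json_round_trip(self, frame, tmp_path):
        from mmii.talairach import TalairachFrame
        frame.save(tmp_path / "f.json")
        back = TalairachFrame.load(tmp_path / "f.json")
        np.testing.assert_allclose(back.axes, frame.axes, atol=1e-12)
        np.testing.assert_allclose(back.ac, frame.ac)


class TestGridCell:
    def test_ac_is_E8a(self, frame):
        c = grid_cell((0, 0, 0), frame)
        assert (c.sector, c.level, c.column) == ("E", 8, "a")
        assert c.in_grid

    def test_ten_percent_anterior_of_vca_is_D(self, frame):
        # 10% of the VCA->anterior span falls in the band abutting VCA
        assert grid_cell((0, 7.0, 5), frame).sector == "D"

    def test_above_superior_bound_flagged(self, frame):
        c = grid_cell((0, 0, 75), frame)
        assert not c.in_grid
        assert c.sector is None

    def test_sector_letters_span_anterior_block(self, frame):
        # proportional 4-way division of [0, 70]
        for y, s in [(5, "D"), (20, "C"), (40, "B"), (65, "A")]:
            assert grid_cell((0, y, 5), frame).sector == s

    def test_levels_above_and_below(self, frame):
        assert grid_cell((0, -5, 69), frame).level == 1   # near vertex
        assert grid_cell((0, -5, 1), frame).level == 8    # just above plane
        assert grid_cell((0, -5, -1), frame).level == 9   # just below
        assert grid_cell((0, -5, -44), frame).level == 12  # deepest

    def test_columns_and_hemisphere(self, frame):
        assert grid_cell((1, -5, 5), frame).column == "a"
        assert grid_cell((60, -5, 5), frame).column == "d"
        assert grid_cell((-60, -5, 5), frame).hemisphere == "left"
        assert grid_cell((60, -5, 5), frame).hemisphere == "right"

    def test_monotone_sectors_moving_anterior(self, frame, rng):
        """Moving strictly anterior never moves the sector label toward
        posterior ones."""
        order = "IHGFEDCBA"
        ys = np.sort(rng.uniform(-79, 69, size=50))
        ranks = [order.index(grid_cell((0, y, 5), frame).sector)
                 for y in ys]
        assert ranks == sorted(ranks)

    def test_partition_tiles_the_box(self, frame, rng):
        """Every in-box point maps to exactly one cell, and the cell
        agrees with from-scratch interval arithmetic."""
        for _ in range(200):
            p = rng.uniform(-1, 1, 3) * [64, 0, 0] + \
                rng.uniform(-1, 1, 3) * [0, 74, 0] + \
                rng.uniform(-1, 1, 3) * [0, 0, 56]
            c = grid_cell(p, frame)
            x, y, z = p
            if not (-80 <= y <= 70 and -45 <= z <= 70 and -65 <= x <= 65):
                assert not c.in_grid
                continue
            # independent interval arithmetic
            if y > 0:
                sec = "DCBA"[min(int(y / (70 / 4)), 3)]
            elif y >= -23:
                sec = "E"
            else:
                sec = "FGHI"[min(int((-y - 23) / ((80 - 23) / 4)), 3)]
            if z >= 0:
                lev = 8 - min(int(z / (70 / 8)), 7)
            else:
                lev = 9 + min(int(-z / (45 / 4)), 3)
            col = "abcd"[min(int(abs(x) / (65 / 4)), 3)]
            assert (c.sector, c.level, c.column) == (sec, lev, col), p


class TestGridPlanes:
    def test_division_counts(self, frame):
        planes = grid_planes(frame)
        d = frame.acpc_distance
        above = [z for z in planes["levels"] if z >= 0]
        below = [z for z in planes["levels"] if z <= 0]
        assert len(above) == 8 + 1   # 8 even bands above the AC-PC plane
        assert len(below) == 4 + 1   # 4 below
        anterior = [y for y in planes["sagittal"] if y >= 0]
        posterior = [y for y in planes["sagittal"] if y <= -d]
        assert len(anterior) == 4 + 1  # A, B, C, D
        assert len(posterior) == 4 + 1  # F, G, H, I

    def test_even_spacing(self, frame):
        planes = grid_planes(frame)
        above = np.diff([z for z in planes["levels"] if z >= 0])
        np.testing.assert_allclose(above, 70 / 8, atol=1e-9)
        cols = np.diff(planes["columns_right"])
        np.testing.assert_allclose(cols, 65 / 4, atol=1e-9)


def test_cell_center_round_trips_through_grid_cell(frame=None):
    frame = build_frame((0, 0, 0), (0, -23, 0), (0, 0, 40),
                        BrainBounds(**BOUNDS))
    for sector in "ABCDEFGHI":
        for level in (1, 8, 9, 12):
            for column in "ad":
                for hemi in ("left", "right"):
                    p = cell_center(sector, level, column, hemi, frame)
                    c = grid_cell(p, frame)
                    assert (c.sector, c.level, c.column, c.hemisphere) == \
                        (sector, level, column, hemi)
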