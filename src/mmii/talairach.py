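"""Talairach proportional grid built from AC, PC and midsagittal landmarks.

The grid is a brain-size-normalized partition of the head defined entirely
by the two commissures, one midsagittal point and the brain bounding box:

* **sagittal sectors** (anterior-posterior): the span between the vertical
  AC plane (VCA) and the anterior brain boundary is divided evenly into 4
  parts lettered A-D; the span between the vertical PC plane (VCP) and the
  posterior boundary into 4 parts F-I; the intercommissural span is the
  single sector E.
* **levels** (superior-inferior): the distance between the AC-PC axial
  plane and the superior boundary is divided evenly into 8 parts, and the
  distance to the inferior boundary into 4 parts, numbered 1 (vertex) to 12
  (deepest).
* **coronal columns** (medial-lateral): each hemisphere's span from the
  midsagittal plane to its lateral boundary is divided evenly into 4 parts
  named a (mesial) to d (lateral).

Letter/number orientation within each block is an atlas convention the
source material leaves open; the defaults here (A most anterior, D abutting
VCA; F abutting VCP, I most posterior; level 1 at the vertex) follow the
original atlas's anterior-to-posterior lettering and vertex-down numbering
and are configurable via :class:`GridConventions`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .errors import GeometryError, ValidationError
from .volumes_io import PointSet

#: Number of even divisions per region: anterior of VCA, posterior of VCP,
#: above the AC-PC plane, below it, and per-hemisphere columns.
N_ANTERIOR_SECTORS = 4
N_POSTERIOR_SECTORS = 4
N_SUPERIOR_LEVELS = 8
N_INFERIOR_LEVELS = 4
N_COLUMNS = 4

ANTERIOR_SECTORS = ("A", "B", "C", "D")   # A most anterior, D abuts VCA
POSTERIOR_SECTORS = ("F", "G", "H", "I")  # F abuts VCP, I most posterior
COLUMNS = ("a", "b", "c", "d")            # a mesial, d lateral


@dataclass
class GridConventions:
    """Configurable letter/number orientation of the grid blocks."""

    anterior_letters_from_front: bool = True  # A most anterior
    levels_from_vertex: bool = True           # level 1 topmost


@dataclass
class BrainBounds:
    """Brain bounding box as positive extents (mm) from the Talairach
    origin (AC) along the frame axes.

    ``anterior`` is the distance from AC (= VCA plane) to the anterior
    boundary, ``posterior`` from AC to the posterior boundary (must exceed
    the AC-PC distance so the posterior bound lies behind VCP),
    ``superior``/``inferior`` from the AC-PC axial plane, and
    ``left``/``right`` from the midsagittal plane.
    """

    anterior: float
    posterior: float
    superior: float
    inferior: float
    left: float
    right: float

    def validate(self, acpc_distance: float) -> None:
        for name in ("anterior", "superior", "inferior", "left", "right"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"bound {name!r} must be > 0")
        if self.posterior <= acpc_distance:
            raise ValidationError(
                "posterior bound must lie posterior to the VCP plane "
                f"(> {acpc_distance:.1f} mm from AC)")


@dataclass
class GridCell:
    """Label of one proportional-grid cell, e.g. sector E, level 8,
    column a, right hemisphere.  ``in_grid`` is False for points outside
    the bounding box (flagged, never an exception)."""

    sector: str | None
    level: int | None
    column: str | None
    hemisphere: str | None
    in_grid: bool = True

    def __str__(self) -> str:
        if not self.in_grid:
            return "out-of-grid"
        return f"{self.sector}{self.level}{self.column}/{self.hemisphere}"


@dataclass
class TalairachFrame:
    """AC/PC/MS landmarks, brain bounds, and the right-handed orthonormal
    triad they induce (x lateral-right, y anterior, z superior; origin AC)."""

    ac: np.ndarray
    pc: np.ndarray
    ms: np.ndarray
    bounds: BrainBounds
    axes: np.ndarray = field(default=None)  # columns: x, y, z unit vectors
    conventions: GridConventions = field(default_factory=GridConventions)

    @property
    def acpc_distance(self) -> float:
        return float(np.linalg.norm(np.asarray(self.ac) - np.asarray(self.pc)))

    def to_frame_coords(self, p: np.ndarray) -> np.ndarray:
        """World mm -> frame coordinates (x right, y anterior of AC,
        z superior of the AC-PC plane)."""
        p = np.atleast_2d(np.asarray(p, dtype=float))
        return (p - self.ac) @ self.axes

    def from_frame_coords(self, q: np.ndarray) -> np.ndarray:
        q = np.atleast_2d(np.asarray(q, dtype=float))
        return q @ self.axes.T + self.ac

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "ac": list(map(float, self.ac)),
            "pc": list(map(float, self.pc)),
            "ms": list(map(float, self.ms)),
            "bounds": {k: float(getattr(self.bounds, k)) for k in
                       ("anterior", "posterior", "superior", "inferior",
                        "left", "right")},
        }, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TalairachFrame":
        d = json.loads(Path(path).read_text())
        return build_frame(d["ac"], d["pc"], d["ms"],
                           BrainBounds(**d["bounds"]))


def build_frame(ac, pc, ms, bounds: BrainBounds,
                conventions: GridConventions | None = None
                ) -> TalairachFrame:
    """Construct the Talairach frame from the three landmarks and the brain
    bounding box.

    y runs along PC->AC (anterior), z is the in-plane component of AC->MS
    orthogonal to y (superior), x = y cross z (lateral right); VCA and VCP
    are the planes perpendicular to the AC-PC line through AC and PC.
    """
    ac = np.asarray(ac, dtype=float)
    pc = np.asarray(pc, dtype=float)
    ms = np.asarray(ms, dtype=float)
    d = np.linalg.norm(ac - pc)
    if d <= 1e-9:
        raise GeometryError("AC and PC coincide")
    y = (ac - pc) / d
    v = ms - ac
    z = v - (v @ y) * y
    nz = np.linalg.norm(z)
    if nz <= 1e-6 * max(1.0, np.linalg.norm(v)):
        raise GeometryError("MS is collinear with the AC-PC line")
    z = z / nz
    x = np.cross(y, z)
    bounds.validate(d)
    axes = np.column_stack([x, y, z])
    return TalairachFrame(ac, pc, ms, bounds, axes,
                          conventions or GridConventions())


def _band(u: float, n: int) -> int:
    """Even-division band index in [0, n) for a proportional position
    u in [0, 1]; half-open bands, inclusive at the u = 0 edge."""
    return min(int(np.floor(u * n)), n - 1)


def grid_cell(p, frame: TalairachFrame) -> GridCell:
    """Assign a world-mm point to its proportional-grid cell.

    Band edges are half-open with the edge closer to the AC-PC plane / VCA
    inclusive, so boundary points resolve deterministically: AC itself is
    sector E, level 8 (the band immediately above the AC-PC plane includes
    the plane), column a.  Hemisphere ties at the midsagittal plane resolve
    to the right.  Out-of-box points get ``in_grid=False``.
    """
    q = frame.to_frame_coords(p)[0]
    xq, yq, zq = q
    b = frame.bounds
    d = frame.acpc_distance
    conv = frame.conventions

    lateral = b.right if xq >= 0 else b.left
    if (yq > b.anterior or yq < -b.posterior or zq > b.superior
            or zq < -b.inferior or xq > b.right or xq < -b.left):
        return GridCell(None, None, None, None, in_grid=False)

    # Sagittal sector: E between VCA (y=0, inclusive) and VCP (y=-d,
    # inclusive); 4 even bands anterior of VCA and posterior of VCP.
    if -d <= yq <= 0:
        sector = "E"
    elif yq > 0:
        i = _band(yq / b.anterior, N_ANTERIOR_SECTORS)  # 0 abuts VCA
        letters = (ANTERIOR_SECTORS[::-1]
                   if conv.anterior_letters_from_front else ANTERIOR_SECTORS)
        sector = letters[i]
    else:
        u = (-yq - d) / (b.posterior - d)
        i = _band(u, N_POSTERIOR_SECTORS)  # 0 abuts VCP
        letters = (POSTERIOR_SECTORS
                   if conv.anterior_letters_from_front
                   else POSTERIOR_SECTORS[::-1])
        sector = letters[i]

    # Level: 8 even bands above the AC-PC plane (plane inclusive), 4 below.
    if zq >= 0:
        i = _band(zq / b.superior, N_SUPERIOR_LEVELS)  # 0 just above plane
        level = (N_SUPERIOR_LEVELS - i if conv.levels_from_vertex else i + 1)
    else:
        i = _band(-zq / b.inferior, N_INFERIOR_LEVELS)
        level = N_SUPERIOR_LEVELS + 1 + i  # 9 just below the plane
    # Column: 4 even bands from midsagittal (inclusive) to the lateral bound.
    hemisphere = "right" if xq >= 0 else "left"
    column = COLUMNS[_band(abs(xq) / lateral, N_COLUMNS)]
    return GridCell(sector, level, column, hemisphere)


def grid_planes(frame: TalairachFrame) -> dict:
    """Dividing planes of the grid, in frame coordinates (mm from AC).

    Returns monotonically sorted plane positions per axis, including the
    region edges (bounding box, VCA, VCP, AC-PC plane, midsagittal plane).
    """
    b = frame.bounds
    d = frame.acpc_distance
    sagittal = np.concatenate([
        np.linspace(-b.posterior, -d, N_POSTERIOR_SECTORS + 1),
        np.linspace(0.0, b.anterior, N_ANTERIOR_SECTORS + 1)])
    levels = np.concatenate([
        np.linspace(-b.inferior, 0.0, N_INFERIOR_LEVELS + 1),
        np.linspace(0.0, b.superior, N_SUPERIOR_LEVELS + 1)[1:]])
    columns_right = np.linspace(0.0, b.right, N_COLUMNS + 1)
    columns_left = np.linspace(-b.left, 0.0, N_COLUMNS + 1)
    return {
        "sagittal": np.unique(sagittal),
        "levels": np.unique(levels),
        "columns_left": columns_left,
        "columns_right": columns_right,
    }


def label_points(ps: PointSet, frame: TalairachFrame) -> pd.DataFrame:
    """Point table with appended sector/level/column/hemisphere columns."""
    rows = []
    for p in ps:
        cell = grid_cell(p.xyz, frame)
        rows.append({
            "name": p.name, "x": p.x, "y": p.y, "z": p.z, "group": p.group,
            "sector": cell.sector, "level": cell.level,
            "column": cell.column, "hemisphere": cell.hemisphere,
            "in_grid": cell.in_grid})
    return pd.DataFrame(rows, columns=["name", "x", "y", "z", "group",
                                       "sector", "level", "column",
                                       "hemisphere", "in_grid"])


def cell_center(sector: str, level: int, column: str, hemisphere: str,
                frame: TalairachFrame) -> np.ndarray:
    """World-mm centre of a named grid cell (used to resolve trajectory
    entry/target points given as Talairach cells)."""
    b = frame.bounds
    d = frame.acpc_distance
    conv = frame.conventions
    if sector == "E":
        y = -d / 2
    elif sector in ANTERIOR_SECTORS:
        letters = (ANTERIOR_SECTORS[::-1]
                   if conv.anterior_letters_from_front else ANTERIOR_SECTORS)
        i = letters.index(sector)
        y = (i + 0.5) * b.anterior / N_ANTERIOR_SECTORS
    elif sector in POSTERIOR_SECTORS:
        letters = (POSTERIOR_SECTORS if conv.anterior_letters_from_front
                   else POSTERIOR_SECTORS[::-1])
        i = letters.index(sector)
        y = -d - (i + 0.5) * (b.posterior - d) / N_POSTERIOR_SECTORS
    else:
        raise ValidationError(f"unknown sector {sector!r}")
    if not 1 <= level <= N_SUPERIOR_LEVELS + N_INFERIOR_LEVELS:
        raise ValidationError(f"level must be 1..12, got {level}")
    if level <= N_SUPERIOR_LEVELS:
        i = (N_SUPERIOR_LEVELS - level if conv.levels_from_vertex
             else level - 1)
        z = (i + 0.5) * b.superior / N_SUPERIOR_LEVELS
    else:
        i = level - N_SUPERIOR_LEVELS - 1
        z = -(i + 0.5) * b.inferior / N_INFERIOR_LEVELS
    if column not in COLUMNS:
        raise ValidationError(f"unknown column {column!r}")
    lateral = b.right if hemisphere == "right" else b.left
    x = (COLUMNS.index(column) + 0.5) * lateral / N_COLUMNS
    if hemisphere == "left":
        x = -x
    return frame.from_frame_coords(np.array([x, y, z]))[0]
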