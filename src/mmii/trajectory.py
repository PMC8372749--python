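"""SEEG trajectory planning: straight entry-target lines, vascular
clearance checks, coverage of localization targets, and the expected
contact positions along each electrode.

A planned electrode is a straight segment from a scalp/skull entry point to
a deep target.  Safety is scored as the minimum distance from the segment
to any vessel voxel of a CTA/MRA-derived mask, with the first 15 mm from
the entry reported separately (vessel injury risk concentrates at the
entry).  The pass/fail clearance threshold defaults to 3 mm and is a
toolkit choice, configurable per case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .volumes_io import (ImageVolume, Point, PointSet,
                         point_segment_distance)

DEFAULT_CLEARANCE_MM = 3.0
ENTRY_ZONE_MM = 15.0


@dataclass
class Trajectory:
    """A straight electrode trajectory from entry to target (world mm)."""

    name: str
    entry: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        self.entry = np.asarray(self.entry, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if not self.name:
            raise ValidationError("trajectory name must be nonempty")
        if self.entry.shape != (3,) or self.target.shape != (3,):
            raise ValidationError("entry and target must be 3-vectors")
        if np.linalg.norm(self.entry - self.target) <= 0:
            raise ValidationError(
                f"trajectory {self.name!r}: entry and target coincide")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.target - self.entry))

    @property
    def direction(self) -> np.ndarray:
        """Unit vector entry -> target."""
        return (self.target - self.entry) / self.length


@dataclass
class SafetyReport:
    """Vessel-clearance summary for one trajectory."""

    name: str
    min_vessel_distance: float
    closest_point_on_trajectory: np.ndarray
    entry_zone_distance: float  # min distance within first 15 mm from entry
    clearance: float
    passed: bool


def plan_trajectory(name: str, entry, target) -> Trajectory:
    """Create a straight-line trajectory; validates distinct endpoints."""
    return Trajectory(name, entry, target)


def vessel_clearance(t: Trajectory, vessels: ImageVolume,
                     clearance: float = DEFAULT_CLEARANCE_MM,
                     entry_zone: float = ENTRY_ZONE_MM) -> SafetyReport:
    """Minimum distance from the trajectory segment to any vessel voxel.

    Vessel voxel centres are taken in world mm from the binary mask.  The
    entry-zone distance is the same minimum restricted to the sub-segment
    covering the first ``entry_zone`` mm from the entry point.  An empty
    mask reports infinite distances and passes.
    """
    mask = np.asarray(vessels.data) > 0
    voxels = np.argwhere(mask)
    if len(voxels) == 0:
        return SafetyReport(t.name, np.inf, t.entry.copy(), np.inf,
                            clearance, True)
    pts = vessels.voxel_to_world(voxels.astype(float))
    d = point_segment_distance(pts, t.entry, t.target)
    i = int(np.argmin(d))
    # closest point on the segment to the nearest vessel voxel
    ab = t.target - t.entry
    s = float(np.clip((pts[i] - t.entry) @ ab / (ab @ ab), 0.0, 1.0))
    closest = t.entry + s * ab
    ez_end = t.entry + min(entry_zone, t.length) * t.direction
    d_entry = point_segment_distance(pts, t.entry, ez_end)
    return SafetyReport(t.name, float(d.min()), closest,
                        float(d_entry.min()), clearance,
                        bool(d.min() >= clearance))


def safety_table(reports: list[SafetyReport]) -> pd.DataFrame:
    return pd.DataFrame([{
        "name": r.name,
        "min_vessel_distance_mm": r.min_vessel_distance,
        "entry_zone_distance_mm": r.entry_zone_distance,
        "closest_x": r.closest_point_on_trajectory[0],
        "closest_y": r.closest_point_on_trajectory[1],
        "closest_z": r.closest_point_on_trajectory[2],
        "clearance_mm": r.clearance,
        "pass": r.passed,
    } for r in reports])


def target_coverage(plan: list[Trajectory], targets: PointSet,
                    radius: float) -> pd.DataFrame:
    """Which trajectories pass within ``radius`` mm of each target point.

    One row per target with the minimal point-to-segment distance, the list
    of covering trajectories, and a covered flag; uncovered points are the
    rows with ``covered == False``.
    """
    if radius <= 0:
        raise ValidationError("coverage radius must be > 0")
    rows = []
    for p in targets:
        dists = {t.name: float(point_segment_distance(
            p.xyz[None], t.entry, t.target)[0]) for t in plan}
        covering = sorted([n for n, d in dists.items() if d <= radius])
        best = min(dists, key=dists.get) if dists else None
        rows.append({
            "target": p.name,
            "min_distance_mm": dists[best] if best else np.inf,
            "nearest_trajectory": best,
            "covering": ",".join(covering),
            "covered": bool(covering)})
    return pd.DataFrame(rows, columns=["target", "min_distance_mm",
                                       "nearest_trajectory", "covering",
                                       "covered"])


def expected_contacts(t: Trajectory, n: int, spacing: float) -> PointSet:
    """Nominal contact centres along a trajectory.

    Contacts are numbered 1..n starting at the target (deepest, the SEEG
    convention) and spaced evenly toward the entry.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if spacing <= 0:
        raise ValidationError("spacing must be > 0")
    span = (n - 1) * spacing
    if span > t.length:
        raise ValidationError(
            f"contact span {span:.1f} mm exceeds trajectory {t.name!r} "
            f"length {t.length:.1f} mm")
    u = -t.direction  # target -> entry
    pts = [Point(f"{t.name}{i + 1}",
                 *(t.target + i * spacing * u), t.name, None)
           for i in range(n)]
    return PointSet(pts)


# ---------------------------------------------------------------------------
# Plan file I/O
# ---------------------------------------------------------------------------

@dataclass
class PlannedElectrode:
    """One electrode of an implantation plan: trajectory plus its contact
    count and spacing."""

    trajectory: Trajectory
    n_contacts: int = 8
    spacing: float = 3.5  # mm, centre to centre


def load_plan(path: str | Path) -> list[PlannedElectrode]:
    """Read an implantation plan from JSON or CSV.

    JSON: list of objects with name, entry [x,y,z], target [x,y,z],
    n_contacts, spacing.  CSV columns: name, entry_x..z, target_x..z,
    n_contacts, spacing.
    """
    path = Path(path)
    if path.suffix == ".json":
        rows = json.loads(path.read_text())
    else:
        df = pd.read_csv(path)
        rows = [{"name": r["name"],
                 "entry": [r["entry_x"], r["entry_y"], r["entry_z"]],
                 "target": [r["target_x"], r["target_y"], r["target_z"]],
                 "n_contacts": r.get("n_contacts", 8),
                 "spacing": r.get("spacing", 3.5)}
                for r in df.to_dict("records")]
    plan = []
    names = set()
    for r in rows:
        if r["name"] in names:
            raise ValidationError(f"duplicate electrode name {r['name']!r}")
        names.add(r["name"])
        plan.append(PlannedElectrode(
            Trajectory(r["name"], r["entry"], r["target"]),
            int(r.get("n_contacts", 8)), float(r.get("spacing", 3.5))))
    return plan


def save_plan(plan: list[PlannedElectrode], path: str | Path) -> None:
    Path(path).write_text(json.dumps([{
        "name": e.trajectory.name,
        "entry": list(map(float, e.trajectory.entry)),
        "target": list(map(float, e.trajectory.target)),
        "n_contacts": e.n_contacts,
        "spacing": e.spacing,
    } for e in plan], indent=1))
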