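"""Electrode-contact segmentation and naming from the post-implant CT.

After the high-resolution post-implant CT is fused with the base T1, the
metal contacts are by far the brightest structures in it.  Candidates are
segmented as 26-connected suprathreshold components; a component long
enough to hold several contacts (touching metal blooms) is split at its 3D
local intensity maxima.  Each candidate's location is its *centre of
maximal intensity* — the intensity-weighted centroid of the component's
top-20% brightest voxels, which is stable under ties and bloom where a
pure argmax is not.

Candidates are then assigned to the nearest planned trajectory (within a
tolerance) and named ``<electrode><index>`` with index 1 at the deepest
(target) end, yielding the named localize-point list that downstream
ictal-onset analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max

from .errors import ValidationError
from .volumes_io import (CONNECTIVITY_26, ImageVolume, Point, PointSet,
                         center_of_max_intensity, point_segment_distance)
from .trajectory import Trajectory

DEFAULT_THRESHOLD_PERCENTILE = 99.9
DEFAULT_ASSIGN_TOL_MM = 4.0


@dataclass
class ElectrodeContact:
    """One named contact: electrode label, 1-based depth index (1 =
    deepest), centre in world mm, and the CT peak intensity."""

    electrode: str
    index: int
    center: np.ndarray
    peak_intensity: float

    @property
    def name(self) -> str:
        return f"{self.electrode}{self.index}"


@dataclass
class ContactSet:
    """Named contacts per electrode plus leftover unassigned candidates."""

    contacts: list[ElectrodeContact] = field(default_factory=list)
    unassigned: PointSet = field(default_factory=PointSet)

    def __post_init__(self) -> None:
        seen = set()
        for c in self.contacts:
            key = (c.electrode, c.index)
            if key in seen:
                raise ValidationError(f"duplicate contact {c.name}")
            seen.add(key)
        for elec in {c.electrode for c in self.contacts}:
            idx = sorted(c.index for c in self.contacts
                         if c.electrode == elec)
            if idx != list(range(1, len(idx) + 1)):
                raise ValidationError(
                    f"electrode {elec!r}: indices not consecutive from 1")

    def electrode(self, name: str) -> list[ElectrodeContact]:
        return sorted((c for c in self.contacts if c.electrode == name),
                      key=lambda c: c.index)

    def as_pointset(self) -> PointSet:
        return PointSet([Point(c.name, *c.center, c.electrode,
                               c.peak_intensity) for c in self.contacts])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "electrode": c.electrode, "index": c.index, "name": c.name,
            "x": c.center[0], "y": c.center[1], "z": c.center[2],
            "peak_intensity": c.peak_intensity,
        } for c in self.contacts], columns=["electrode", "index", "name",
                                            "x", "y", "z",
                                            "peak_intensity"])


def segment_contact_candidates(ct: ImageVolume,
                               threshold: float | None = None,
                               percentile: float =
                               DEFAULT_THRESHOLD_PERCENTILE,
                               expected_spacing: float = 3.5,
                               min_voxels: int = 1) -> PointSet:
    """Segment contact candidates from a base-frame post-implant CT.

    ``threshold`` is an absolute intensity; when None, the given intensity
    percentile of the volume is used (default 99.9th — appropriate when the
    CT calibration is unknown; clinical metal is better isolated with an
    absolute threshold).  Components whose suprathreshold extent spans more
    than one nominal contact are split at 3D local maxima separated by at
    least 0.7 x ``expected_spacing``.
    """
    data = np.asarray(ct.data, dtype=float)
    if threshold is None:
        threshold = float(np.percentile(data, percentile))
    mask = data > threshold
    labels, n = ndimage.label(mask, structure=CONNECTIVITY_26)
    min_sep_vox = max(1, int(np.floor(
        0.7 * expected_spacing / float(ct.voxel_size.min()))))
    candidates: list[tuple[float, np.ndarray]] = []
    for lab in range(1, n + 1):
        voxels = np.argwhere(labels == lab)
        if len(voxels) < min_voxels:
            continue
        candidates.extend(_component_centers(data, voxels, labels, lab,
                                             min_sep_vox, ct))
    candidates.sort(key=lambda c: (-c[0], tuple(c[1])))
    return PointSet([Point(f"C{i + 1}", *xyz, "candidate", peak)
                     for i, (peak, xyz) in enumerate(candidates)])


def _component_centers(data, voxels, labels, lab, min_sep_vox, ct):
    """One centre per contact in a component, splitting merged blooms at
    local maxima."""
    comp_mask = labels == lab
    peaks = peak_local_max(np.where(comp_mask, data, 0.0),
                           min_distance=min_sep_vox, exclude_border=False)
    peaks = peaks[comp_mask[tuple(peaks.T)]]
    out = []
    if len(peaks) <= 1:
        center = center_of_max_intensity(data, voxels)
        out.append((float(data[tuple(voxels.T)].max()),
                    ct.voxel_to_world(center)[0]))
        return out
    # partition component voxels by nearest local maximum
    d2 = ((voxels[:, None, :] - peaks[None, :, :]) ** 2).sum(axis=2)
    owner = np.argmin(d2, axis=1)
    for k in range(len(peaks)):
        part = voxels[owner == k]
        if len(part) == 0:
            continue
        center = center_of_max_intensity(data, part)
        out.append((float(data[tuple(part.T)].max()),
                    ct.voxel_to_world(center)[0]))
    return out


def assign_and_name(candidates: PointSet, plan: list[Trajectory],
                    tol: float = DEFAULT_ASSIGN_TOL_MM) -> ContactSet:
    """Assign each candidate to its nearest planned trajectory and name the
    contacts ``<electrode><index>`` with index 1 at the target (deepest) end.

    A candidate farther than ``tol`` mm from every trajectory goes to the
    unassigned list.  Per electrode, contacts are ordered by their scalar
    projection onto the trajectory axis from target toward entry; ties are
    broken by distance to the axis, then lexicographically by coordinates,
    so the output is deterministic and independent of candidate order.
    """
    if not plan:
        raise ValidationError("plan must contain at least one trajectory")
    if tol <= 0:
        raise ValidationError("tol must be > 0")
    names = [t.name for t in plan]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate trajectory names in plan")

    per_elec: dict[str, list[tuple[float, float, tuple, Point]]] = \
        {t.name: [] for t in plan}
    unassigned = []
    for p in candidates:
        dists = [float(point_segment_distance(p.xyz[None], t.entry,
                                              t.target)[0]) for t in plan]
        i = int(np.argmin(dists))
        if dists[i] > tol:
            unassigned.append(p)
            continue
        t = plan[i]
        u = -t.direction  # target -> entry
        proj = float((p.xyz - t.target) @ u)
        per_elec[t.name].append((proj, dists[i], tuple(p.xyz), p))

    contacts = []
    for t in plan:
        entries = sorted(per_elec[t.name])
        for idx, (_, _, _, p) in enumerate(entries, start=1):
            contacts.append(ElectrodeContact(
                t.name, idx, p.xyz,
                p.value if p.value is not None else np.nan))
    return ContactSet(contacts, PointSet(unassigned))
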