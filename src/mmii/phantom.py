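"""Synthetic, ground-truthed head phantoms for every stage of the workflow.

The phantoms are geometric, not anatomically realistic: every operator in
the toolkit depends only on geometry, intensity contrast and noise, so
ellipsoidal heads with a skull shell, gray/white bands and ventricles are
sufficient and keep tests fast.  Four generators cover the four acquisition
families the workflow consumes:

* :func:`make_t1_phantom` — the anatomical base volume, with AC/PC/MS truth
  (inter-commissural distance defaults to 23 mm, mid-range for adults).
* :func:`make_perfusion_pair` — SPECT-like ictal/interictal volumes:
  smoothed brain-proportional activity with Poisson counting noise, the
  ictal volume carrying focal multiplicative perfusion changes.
* :func:`make_implant_ct` — CT-like volume with bright quasi-spherical
  contacts along a known implantation plan (sub-voxel jitter, sigma = 0.2
  voxel), plus the exact truth contact list.
* :func:`make_vessel_mask` — smooth random tubes inside the head with exact
  centerline truth.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .errors import ValidationError
from .trajectory import PlannedElectrode, Trajectory, expected_contacts
from .contacts import ContactSet, ElectrodeContact
from .volumes_io import ImageVolume, Point, PointSet


@dataclass
class PhantomSpec:
    """Geometry, intensity and noise parameters of a synthetic case."""

    dims: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 2.0  # mm, isotropic
    seed: int = 0
    acpc_distance: float = 23.0  # mm, adult mid-range
    blob_specs: list[tuple] = field(default_factory=list)
    # (center mm, radius mm, fractional change), e.g. ((10,0,20), 8, 0.15)
    implant_plan: list[PlannedElectrode] = field(default_factory=list)
    vessel_spec: tuple[int, float, float] = (3, 2.0, 0.3)
    # (n_tubes, radius mm, tortuosity 0..1)
    noise_sigma: float = 2.0     # Gaussian noise for MRI/CT
    perfusion_counts: float = 200.0  # mean brain counts per voxel

    def __post_init__(self) -> None:
        if min(self.dims) < 32:
            raise ValidationError("phantom dims must be >= 32 per axis")
        if self.voxel_size <= 0:
            raise ValidationError("voxel_size must be > 0")
        if not 20.0 <= self.acpc_distance <= 28.0:
            raise ValidationError("AC-PC distance must be in [20, 28] mm")

    @property
    def affine(self) -> np.ndarray:
        """Isotropic RAS affine with the world origin at the volume centre."""
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = -(np.array(self.dims) - 1) * self.voxel_size / 2.0
        return aff

    @property
    def fov_mm(self) -> np.ndarray:
        return np.array(self.dims) * self.voxel_size

    def landmark_truth(self) -> dict:
        h = self.acpc_distance / 2.0
        return {"ac": [0.0, h, 0.0], "pc": [0.0, -h, 0.0],
                "ms": [0.0, h, 0.35 * float(self.fov_mm[2]) / 2.0]}


def _world_grid(spec: PhantomSpec) -> tuple[np.ndarray, ...]:
    aff = spec.affine
    axes = [aff[i, i] * np.arange(spec.dims[i]) + aff[i, 3]
            for i in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(grid, center, radii) -> np.ndarray:
    x, y, z = grid
    cx, cy, cz = center
    rx, ry, rz = radii
    return (((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2
            + ((z - cz) / rz) ** 2) <= 1.0


#: Brain semi-axes as fractions of the field of view.  Deliberately
#: anisotropic (longer front-to-back, as real brains are) so that rigid
#: rotations are identifiable from the outer contour alone.
BRAIN_AXIS_FRACTIONS = np.array([0.30, 0.36, 0.26])


def brain_radii(spec: PhantomSpec) -> np.ndarray:
    """Analytic semi-axes of the brain ellipsoid (mm)."""
    return BRAIN_AXIS_FRACTIONS * spec.fov_mm


def make_t1_phantom(spec: PhantomSpec) -> tuple[ImageVolume, dict]:
    """Ellipsoidal head with skull shell, gray/white brain bands and
    ventricles; returns the volume and a truth record with AC/PC/MS and the
    analytic brain geometry."""
    rng = np.random.default_rng(spec.seed)
    grid = _world_grid(spec)
    b_r = brain_radii(spec)
    head_r = 0.42 * spec.fov_mm
    skull_r = 0.38 * spec.fov_mm

    data = np.zeros(spec.dims, dtype=float)
    data[_ellipsoid(grid, (0, 0, 0), head_r)] = 30.0      # scalp/soft tissue
    skull = _ellipsoid(grid, (0, 0, 0), skull_r)
    data[skull] = 10.0                                    # skull (dark on T1)
    brain = _ellipsoid(grid, (0, 0, 0), b_r)
    data[brain] = 100.0                                   # white matter
    gray = brain & ~_ellipsoid(grid, (0, 0, 0), 0.85 * b_r)
    data[gray] = 70.0                                     # cortical band
    vent_r = 0.12 * b_r
    for side in (-1, 1):  # anterior offset breaks front-back symmetry
        vent = _ellipsoid(grid,
                          (side * 0.15 * b_r[0], 0.15 * b_r[1],
                           0.1 * b_r[2]), vent_r)
        data[vent] = 20.0                                 # CSF
    data += rng.normal(0.0, spec.noise_sigma, size=spec.dims)
    data = np.clip(data, 0.0, None)

    truth = dict(spec.landmark_truth())
    truth.update({"brain_radii": b_r.tolist(), "brain_center": [0, 0, 0],
                  "head_radii": head_r.tolist(), "seed": spec.seed})
    vol = ImageVolume(data, spec.affine, "t1", "base")
    return vol, truth


def brain_mask_volume(spec: PhantomSpec) -> ImageVolume:
    """Analytic brain-ellipsoid mask on the phantom grid."""
    grid = _world_grid(spec)
    mask = _ellipsoid(grid, (0, 0, 0), brain_radii(spec))
    return ImageVolume(mask.astype(np.uint8), spec.affine, "mask", "base")


def make_perfusion_pair(spec: PhantomSpec
                        ) -> tuple[ImageVolume, ImageVolume, ImageVolume,
                                   dict]:
    """SPECT-like ictal/interictal pair with known focal perfusion changes.

    The noiseless activity is brain-proportional (cortex above white
    matter), smoothed to SPECT-like resolution; the ictal volume multiplies
    in each blob's fractional change before Poisson counting noise is
    drawn.  Returns (ictal, interictal, brain mask, truth).
    """
    rng = np.random.default_rng(spec.seed)
    grid = _world_grid(spec)
    b_r = brain_radii(spec)
    brain = _ellipsoid(grid, (0, 0, 0), b_r)
    activity = np.where(brain, 0.75 * spec.perfusion_counts, 0.0)
    gray = brain & ~_ellipsoid(grid, (0, 0, 0), 0.85 * b_r)
    activity[gray] = spec.perfusion_counts
    activity = ndimage.gaussian_filter(activity, 1.2)  # camera resolution

    ictal_activity = activity.copy()
    x, y, z = grid
    for center, radius, change in spec.blob_specs:
        c = np.asarray(center, dtype=float)
        if np.any(np.abs(c) / b_r + radius / b_r > 1.0):
            raise ValidationError(f"blob at {center} extends outside brain")
        blob = ((x - c[0]) ** 2 + (y - c[1]) ** 2
                + (z - c[2]) ** 2) <= radius ** 2
        ictal_activity[blob] *= (1.0 + change)

    ictal = rng.poisson(ictal_activity).astype(float)
    interictal = rng.poisson(activity).astype(float)
    truth = {"blobs": [{"center": list(map(float, c)), "radius": float(r),
                        "change": float(ch)}
                       for c, r, ch in spec.blob_specs],
             "seed": spec.seed}
    aff = spec.affine
    return (ImageVolume(ictal, aff, "spect", "base"),
            ImageVolume(interictal, aff, "spect", "base"),
            ImageVolume(brain.astype(np.uint8), aff, "mask", "base"),
            truth)


#: CT-like intensities (arbitrary HU-like units).
CT_TISSUE, CT_SKULL, CT_CONTACT = 40.0, 1000.0, 3000.0


def make_implant_ct(spec: PhantomSpec) -> tuple[ImageVolume, ContactSet]:
    """CT-like volume with bright quasi-spherical contacts along the
    implantation plan; returns the volume and the exact truth ContactSet.

    Contact centres are the nominal :func:`expected_contacts` positions
    plus sub-voxel Gaussian jitter (sigma = 0.2 voxel); each contact is
    rendered as a partial-volume-weighted sphere of 1.5 mm radius so the
    sub-voxel centre is recoverable from the intensity profile.
    """
    rng = np.random.default_rng(spec.seed)
    grid = _world_grid(spec)
    b_r = brain_radii(spec)
    head_r = 0.44 * spec.fov_mm
    skull_outer = 0.395 * spec.fov_mm

    data = np.zeros(spec.dims, dtype=float)
    data[_ellipsoid(grid, (0, 0, 0), head_r)] = CT_TISSUE
    skull = (_ellipsoid(grid, (0, 0, 0), skull_outer)
             & ~_ellipsoid(grid, (0, 0, 0), 0.365 * spec.fov_mm))
    data[skull] = CT_SKULL

    truth_contacts = []
    xg, yg, zg = grid
    for e in spec.implant_plan:
        nominal = expected_contacts(e.trajectory, e.n_contacts, e.spacing)
        axis = e.trajectory.direction
        for i, p in enumerate(nominal, start=1):
            # lateral-only jitter: the shaft fixes the axial spacing, so
            # sub-voxel deviations are perpendicular to the trajectory
            j = rng.normal(0.0, 0.2 * spec.voxel_size, size=3)
            c = p.xyz + j - (j @ axis) * axis
            d2 = (xg - c[0]) ** 2 + (yg - c[1]) ** 2 + (zg - c[2]) ** 2
            # smooth partial-volume profile of a 1.5 mm metal bead;
            # metal composes by maximum, so adjacent blooms never saturate
            # into a single plateau
            data = np.maximum(data, CT_CONTACT * np.clip(
                (1.5 + 0.5 * spec.voxel_size - np.sqrt(d2))
                / spec.voxel_size, 0.0, 1.0))
            truth_contacts.append(ElectrodeContact(
                e.trajectory.name, i, c, CT_CONTACT))
    data += rng.normal(0.0, spec.noise_sigma, size=spec.dims)
    vol = ImageVolume(data, spec.affine, "ct", "base")
    return vol, ContactSet(truth_contacts)


def make_vessel_mask(spec: PhantomSpec
                     ) -> tuple[ImageVolume, list[PointSet]]:
    """Random smooth tubes inside the head; binary mask plus exact
    centerline polylines (one PointSet per tube)."""
    n_tubes, radius, tortuosity = spec.vessel_spec
    if radius < spec.voxel_size:
        raise ValidationError("vessel radius must be >= 1 voxel")
    rng = np.random.default_rng(spec.seed)
    b_r = brain_radii(spec)
    mask = np.zeros(spec.dims, dtype=bool)
    base = ImageVolume(mask.astype(np.uint8), spec.affine, "mask", "base")
    centerlines = []
    for k in range(n_tubes):
        # smooth curve through jittered control points across the brain
        t_ctrl = np.linspace(0.0, 1.0, 5)
        start = rng.uniform(-0.7, 0.7, size=3) * b_r
        end = rng.uniform(-0.7, 0.7, size=3) * b_r
        ctrl = np.outer(1 - t_ctrl, start) + np.outer(t_ctrl, end)
        ctrl[1:-1] += rng.normal(0.0, tortuosity * 0.25 * b_r.min(),
                                 size=(3, 3))
        curve = CubicSpline(t_ctrl, ctrl, axis=0)(np.linspace(0, 1, 60))
        pts = [Point(f"V{k}_{i}", *c, f"V{k}", None)
               for i, c in enumerate(curve)]
        centerlines.append(PointSet(pts))
        for a, b in zip(curve[:-1], curve[1:]):
            _stamp_tube(mask, base, a, b, radius)
    return (ImageVolume(mask.astype(np.uint8), spec.affine, "cta", "base"),
            centerlines)


def _stamp_tube(mask, base, a, b, radius):
    from .volumes_io import point_segment_distance
    va, vb = base.world_to_voxel(a)[0], base.world_to_voxel(b)[0]
    pad = np.ceil(radius / base.voxel_size).astype(int) + 1
    lo = np.maximum(np.floor(np.minimum(va, vb)).astype(int) - pad, 0)
    hi = np.minimum(np.ceil(np.maximum(va, vb)).astype(int) + pad + 1,
                    mask.shape)
    if np.any(lo >= hi):
        return
    grid = np.stack(np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                                indexing="ij"), axis=-1).reshape(-1, 3)
    world = base.voxel_to_world(grid)
    keep = point_segment_distance(world, np.asarray(a, float),
                                  np.asarray(b, float)) <= radius
    sel = grid[keep]
    mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True


def default_implant_plan(spec: PhantomSpec) -> list[PlannedElectrode]:
    """Three parallel-ish depth electrodes, 8 contacts at 3.5 mm, fitting
    inside the phantom brain."""
    b_r = brain_radii(spec)
    plans = []
    for i, (name, yoff, zoff) in enumerate(
            [("LA", 0.35, 0.0), ("LB", 0.0, 0.25), ("LC", -0.35, -0.1)]):
        entry = np.array([-0.9 * b_r[0], yoff * b_r[1], zoff * b_r[2]])
        target = np.array([0.55 * b_r[0], yoff * b_r[1], zoff * b_r[2]])
        plans.append(PlannedElectrode(Trajectory(name, entry, target),
                                      n_contacts=8, spacing=3.5))
    return plans


def write_full_case(out_dir: str | Path, seed: int = 0,
                    dims: tuple[int, int, int] = (64, 64, 64),
                    voxel_size: float = 2.0) -> dict:
    """Write a complete phantom case (T1, perfusion pair, implant CT,
    vessel mask, plan.json, truth.json) and return the truth record.

    The implant CT is generated on a finer grid (1.25 mm) than the base so
    contact spacing is resolvable, as in clinical acquisitions.
    """
    from .volumes_io import write_volume
    from .trajectory import save_plan

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = PhantomSpec(dims=dims, voxel_size=voxel_size, seed=seed,
                       blob_specs=[((15.0, 0.0, 15.0), 8.0, 0.15)])
    t1, t1_truth = make_t1_phantom(spec)
    ictal, interictal, brain_mask, perf_truth = make_perfusion_pair(spec)

    ct_dims = tuple(int(round(d * voxel_size / 1.25)) for d in dims)
    ct_spec = PhantomSpec(dims=ct_dims, voxel_size=1.25, seed=seed + 1)
    plan = default_implant_plan(ct_spec)
    ct_spec.implant_plan = plan
    ct, contact_truth = make_implant_ct(ct_spec)
    vessels, centerlines = make_vessel_mask(spec)

    write_volume(t1, out / "t1.nii.gz")
    write_volume(ictal, out / "spect_ictal.nii.gz")
    write_volume(interictal, out / "spect_interictal.nii.gz")
    write_volume(brain_mask, out / "brain_mask.nii.gz")
    write_volume(ct, out / "implant_ct.nii.gz")
    write_volume(vessels, out / "vessels.nii.gz")
    save_plan(plan, out / "plan.json")

    truth = {
        "landmarks": t1_truth,
        "perfusion": perf_truth,
        "contacts": [{"electrode": c.electrode, "index": c.index,
                      "center": list(map(float, c.center))}
                     for c in contact_truth.contacts],
        "seed": seed,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return truth
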