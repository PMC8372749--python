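"""Volumes, point sets and burn-to-volume round trips.

The universal carrier for every modality is :class:`ImageVolume`: a 3D scalar
grid plus a voxel-index -> world-millimetre affine.  World coordinates are
RAS+ millimetres, voxel indices are 0-based, and the affine follows the NIfTI
convention throughout the toolkit.

Point and line annotations travel between this toolkit and DICOM-consuming
systems (neuronavigation, review workstations) as *burned-in* high-intensity
features on an anatomical volume: :func:`burn_points` /
:func:`extract_bright_points` implement that round trip for localize points
(MEG dipoles, electrode contacts, markers), :func:`burn_lines` for planned
electrode trajectories.
"""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy import ndimage

from .errors import FormatError, ValidationError

#: 26-neighbourhood connectivity used for every connected-component step.
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)

MODALITIES = ("t1", "t2", "flair", "pet", "spect", "ct", "cta", "map",
              "fmri", "mask", "other")

_DICOM_MODALITY_MAP = {"CT": "ct", "PT": "pet", "NM": "spect"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ImageVolume:
    """A 3D scalar grid with a voxel-index -> world-mm affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities; units are modality dependent.
    affine : ndarray, shape (4, 4)
        Maps 0-based voxel indices (homogeneous) to RAS+ world millimetres.
    modality : str
        One of ``t1 | t2 | flair | pet | spect | ct | cta | map | fmri |
        mask | other``.
    frame_id : str
        Label of the coordinate frame the volume lives in; ``"base"`` after
        registration onto the base T1.
    """

    data: np.ndarray
    affine: np.ndarray
    modality: str = "other"
    frame_id: str = "native"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError(
                f"volume data must be 3D with every axis >= 1, got shape "
                f"{self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is singular")
        if np.any(self.voxel_size <= 0):
            raise ValidationError("voxel spacings must all be > 0")
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality tag {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel spacing (mm) along each index axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to (N, 3) world mm."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (N, 3) world mm to (N, 3) continuous voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def contains_world(self, xyz: np.ndarray) -> np.ndarray:
        """Boolean mask: does each world point fall inside the grid?"""
        v = self.world_to_voxel(xyz)
        upper = np.array(self.shape) - 0.5
        return np.all((v >= -0.5) & (v < upper), axis=1)

    def copy(self, data: np.ndarray | None = None) -> "ImageVolume":
        return ImageVolume(
            self.data.copy() if data is None else data,
            self.affine.copy(), self.modality, self.frame_id)

    def world_grid(self) -> np.ndarray:
        """World mm coordinates of every voxel centre, shape (*shape, 3)."""
        idx = np.indices(self.shape, dtype=float)
        ijk = np.stack(idx, axis=-1).reshape(-1, 3)
        return self.voxel_to_world(ijk).reshape(*self.shape, 3)


@dataclass
class RigidTransform:
    """A 4x4 homogeneous world -> world rigid mapping in millimetres."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValidationError("transform matrix must be 4x4")
        R = self.matrix[:3, :3]
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValidationError("rotation block is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValidationError("rotation block must have determinant +1")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1], atol=1e-9):
            raise ValidationError("last row must be [0, 0, 0, 1]")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_params(cls, rx: float, ry: float, rz: float,
                    tx: float, ty: float, tz: float,
                    center: Sequence[float] = (0.0, 0.0, 0.0),
                    degrees: bool = True) -> "RigidTransform":
        """Euler-angle construction: R = Rz @ Ry @ Rx about ``center``."""
        if degrees:
            rx, ry, rz = np.deg2rad([rx, ry, rz])
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        R = Rz @ Ry @ Rx
        c = np.asarray(center, dtype=float)
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = np.array([tx, ty, tz]) + c - R @ c
        return cls(m)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return xyz @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "RigidTransform":
        return RigidTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self @ other).apply(p) = self(other(p))."""
        return RigidTransform(self.matrix @ other.matrix)

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    @property
    def rotation_angle_deg(self) -> float:
        """Total rotation angle (degrees) of the rotation block."""
        tr = np.trace(self.matrix[:3, :3])
        return float(np.degrees(np.arccos(np.clip((tr - 1) / 2, -1, 1))))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps({"matrix": self.matrix.tolist()},
                                       indent=1))
        else:
            np.savetxt(path, self.matrix, fmt="%.12g")

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        path = Path(path)
        if path.suffix == ".json":
            return cls(np.asarray(json.loads(path.read_text())["matrix"]))
        return cls(np.loadtxt(path))


class Point(NamedTuple):
    name: str
    x: float
    y: float
    z: float
    group: str = ""
    value: float | None = None

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class PointSet:
    """Named 3D points in world millimetres (a "localize points" list)."""

    points: list[Point] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = [p if isinstance(p, Point) else Point(*p)
                       for p in self.points]
        names = [p.name for p in self.points]
        dupes = sorted({n for n in names if names.count(n) > 1})
        if dupes:
            raise ValidationError(f"duplicate point names: {dupes}")
        coords = self.coords
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValidationError("point coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def __getitem__(self, name: str) -> Point:
        for p in self.points:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.points]

    @property
    def coords(self) -> np.ndarray:
        if not self.points:
            return np.empty((0, 3))
        return np.array([[p.x, p.y, p.z] for p in self.points])

    def subset(self, group: str) -> "PointSet":
        return PointSet([p for p in self.points if p.group == group])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [p._asdict() for p in self.points],
            columns=["name", "x", "y", "z", "group", "value"])


@dataclass
class BurnSettings:
    """How point/line annotations are burned into a volume.

    Burned intensity is *relative to the volume's global maximum* so that the
    same settings work across MRI and CT dynamic ranges, and burned features
    remain strictly brighter than any anatomy (hence re-segmentable).
    """

    marker_radius: float = 2.0   # mm
    marker_intensity: float = 1.2  # x global max, must be > 1
    line_radius: float = 1.0     # mm

    def __post_init__(self) -> None:
        if self.marker_radius <= 0 or self.line_radius <= 0:
            raise ValidationError("burn radii must be > 0")
        if self.marker_intensity <= 1:
            raise ValidationError("marker_intensity must be > 1")


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, modality: str | None = None) -> ImageVolume:
    """Read a NIfTI-1 file or a directory holding one DICOM series.

    DICOM slices are assembled in spatial order (sorted by
    ImagePositionPatient projected on the slice normal) and converted from
    DICOM LPS to RAS+ world coordinates.  The modality tag is inferred from
    metadata where possible, else set to ``"other"``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    if path.is_dir():
        return _read_dicom_series(path, modality)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {data.shape}")
    return ImageVolume(np.asarray(data, dtype=float), np.asarray(img.affine),
                       modality or "other")


def _read_dicom_series(directory: Path, modality: str | None) -> ImageVolume:
    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:
            raise FormatError(f"unreadable DICOM file {f}: {exc}") from exc
        if not hasattr(ds, "PixelData"):
            raise FormatError(f"{f} carries no pixel data")
        slices.append((f, ds))
    if not slices:
        raise FormatError(f"no DICOM files in {directory}")
    series_uids = {getattr(ds, "SeriesInstanceUID", None) for _, ds in slices}
    if len(series_uids) > 1:
        bad = [str(f) for f, ds in slices
               if ds.SeriesInstanceUID != slices[0][1].SeriesInstanceUID]
        raise FormatError(f"mixed DICOM series; offending files: {bad}")

    ds0 = slices[0][1]
    iop = np.array(ds0.ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]  # across a row / down a column
    normal = np.cross(col_dir, row_dir)  # + along the volume's third axis
    positions = [np.array(ds.ImagePositionPatient, dtype=float)
                 for _, ds in slices]
    proj = [float(p @ normal) for p in positions]
    order = np.argsort(proj, kind="stable")
    proj_sorted = np.array(proj)[order]
    if len(proj_sorted) > 1 and np.min(np.diff(proj_sorted)) < 1e-6:
        raise FormatError("duplicate slice positions (tied projections) in "
                          f"{directory}")
    slices = [slices[i] for i in order]
    positions = [positions[i] for i in order]

    arr = np.stack([s[1].pixel_array for s in slices], axis=-1).astype(float)
    for _, ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        if slope != 1.0 or inter != 0.0:
            arr = arr * slope + inter
            break  # assume uniform rescale across the series

    ps = np.array(ds0.PixelSpacing, dtype=float)  # [row spacing, col spacing]
    if len(slices) > 1:
        slice_vec = positions[1] - positions[0]
    else:
        thickness = float(getattr(ds0, "SliceThickness", 1.0))
        slice_vec = normal * thickness
    # data axes: (row index, col index, slice index); DICOM world is LPS.
    affine_lps = np.eye(4)
    affine_lps[:3, 0] = col_dir * ps[0]
    affine_lps[:3, 1] = row_dir * ps[1]
    affine_lps[:3, 2] = slice_vec
    affine_lps[:3, 3] = positions[0]
    lps_to_ras = np.diag([-1.0, -1.0, 1.0, 1.0])
    affine = lps_to_ras @ affine_lps

    if modality is None:
        modality = _DICOM_MODALITY_MAP.get(getattr(ds0, "Modality", ""), None)
        if modality is None and getattr(ds0, "Modality", "") == "MR":
            desc = str(getattr(ds0, "SeriesDescription", "")).lower()
            for tag in ("t1", "t2", "flair"):
                if tag in desc:
                    modality = tag
                    break
        modality = modality or "other"
    return ImageVolume(arr, affine, modality)


def write_volume(vol: ImageVolume, path: str | Path,
                 format: str = "nifti") -> None:
    """Write a volume as NIfTI (single file) or as a DICOM series (directory).

    The round trip ``read_volume(write_volume(vol))`` reproduces the data
    within dtype rounding and the affine within 1e-3 mm.
    """
    path = Path(path)
    if format == "nifti":
        img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32),
                              vol.affine)
        try:
            nib.save(img, str(path))
        except Exception as exc:
            raise OSError(f"cannot write NIfTI to {path}: {exc}") from exc
    elif format == "dicom_series":
        _write_dicom_series(vol, path)
    else:
        raise ValidationError(f"unknown format {format!r}")


def _write_dicom_series(vol: ImageVolume, directory: Path) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    ras_to_lps = np.diag([-1.0, -1.0, 1.0, 1.0])
    aff = ras_to_lps @ vol.affine
    col_dir = aff[:3, 0] / np.linalg.norm(aff[:3, 0])
    row_dir = aff[:3, 1] / np.linalg.norm(aff[:3, 1])
    ps = [float(np.linalg.norm(aff[:3, 0])), float(np.linalg.norm(aff[:3, 1]))]
    slice_vec = aff[:3, 2]

    data = np.asarray(vol.data, dtype=float)
    lo, hi = float(data.min()), float(data.max())
    slope = (hi - lo) / 65535.0 if hi > lo else 1.0
    stored = np.round((data - lo) / slope).astype(np.uint16)

    series_uid = generate_uid()
    study_uid = generate_uid()
    modality = {"ct": "CT", "pet": "PT", "spect": "NM"}.get(vol.modality, "MR")
    now = datetime.datetime(2000, 1, 1)  # fixed stamp: deterministic output
    for s in range(vol.shape[2]):
        ds = FileDataset(None, {}, file_meta=FileMetaDataset(),
                         preamble=b"\x00" * 128)
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = \
            "1.2.840.10008.5.1.4.1.1.7"  # secondary capture
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.SOPClassUID = ds.file_meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.PatientName = "PHANTOM"
        ds.PatientID = "MMII"
        ds.Modality = modality
        ds.SeriesDescription = vol.modality
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.ContentDate = now.strftime("%Y%m%d")
        ds.ContentTime = now.strftime("%H%M%S")
        ds.InstanceNumber = s + 1
        ds.ImageOrientationPatient = [float(v) for v in
                                      np.concatenate([row_dir, col_dir])]
        ipp = aff[:3, 3] + s * slice_vec
        ds.ImagePositionPatient = [float(v) for v in ipp]
        ds.PixelSpacing = ps
        ds.SliceThickness = float(np.linalg.norm(slice_vec))
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows, ds.Columns = vol.shape[0], vol.shape[1]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = slope
        ds.RescaleIntercept = lo
        ds.PixelData = np.ascontiguousarray(stored[:, :, s]).tobytes()
        ds.save_as(str(directory / f"slice{s:04d}.dcm"),
                   enforce_file_format=True)


# ---------------------------------------------------------------------------
# Burn / extract round trip
# ---------------------------------------------------------------------------

def burn_points(vol: ImageVolume, pts: PointSet,
                s: BurnSettings | None = None) -> ImageVolume:
    """Print points as high-intensity spheres on top of a volume.

    Voxels within ``marker_radius`` (mm, measured between world-space voxel
    centres and the point) are set to ``marker_intensity`` x the *original*
    global maximum; no voxel outside those spheres changes.  Points outside
    the field of view raise a per-point warning and are skipped.
    """
    s = s or BurnSettings()
    out = vol.copy()
    if not len(pts):
        return out
    burn_val = s.marker_intensity * float(vol.data.max())
    inside = vol.contains_world(pts.coords)
    for p, ok in zip(pts, inside):
        if not ok:
            warnings.warn(f"point {p.name!r} outside field of view; skipped")
            continue
        sel = _sphere_voxels(vol, p.xyz, s.marker_radius)
        out.data[sel] = burn_val
    return out


def _sphere_voxels(vol: ImageVolume, center: np.ndarray, radius: float):
    """Index arrays of voxels whose world centre lies within ``radius`` mm."""
    cv = vol.world_to_voxel(center)[0]
    pad = np.ceil(radius / vol.voxel_size).astype(int) + 1
    lo = np.maximum(np.floor(cv).astype(int) - pad, 0)
    hi = np.minimum(np.floor(cv).astype(int) + pad + 1, vol.shape)
    if np.any(lo >= hi):
        return tuple(np.empty(0, dtype=int) for _ in range(3))
    grid = np.stack(np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                                indexing="ij"), axis=-1).reshape(-1, 3)
    world = vol.voxel_to_world(grid)
    keep = np.linalg.norm(world - center, axis=1) <= radius
    sel = grid[keep]
    return sel[:, 0], sel[:, 1], sel[:, 2]


def center_of_max_intensity(data: np.ndarray, voxels: np.ndarray,
                            top_fraction: float = 0.2) -> np.ndarray:
    """Centre of maximal intensity of a voxel component.

    Intensity-weighted centroid of the top ``top_fraction`` brightest voxels
    of the component — robust to ties and bloom, unlike a pure argmax.  This
    is the rule used both for electrode-contact centres and for re-segmented
    burned markers.  Returns continuous voxel coordinates.
    """
    voxels = np.asarray(voxels)
    vals = data[voxels[:, 0], voxels[:, 1], voxels[:, 2]].astype(float)
    cutoff = np.quantile(vals, 1.0 - top_fraction) if len(vals) > 1 else vals[0]
    keep = vals >= cutoff
    w = vals[keep]
    if w.sum() <= 0:
        w = np.ones_like(w)
    return (voxels[keep] * w[:, None]).sum(axis=0) / w.sum()


def extract_bright_points(vol: ImageVolume, threshold: float) -> PointSet:
    """Segment suprathreshold blobs back into a list of localize points.

    26-connected components of voxels strictly above ``threshold``; one point
    per component at its centre of maximal intensity, in world mm.  Points
    are named ``P1, P2, ...`` ordered by descending peak intensity.
    """
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    mask = vol.data > threshold
    labels, n = ndimage.label(mask, structure=CONNECTIVITY_26)
    comps = []
    for lab in range(1, n + 1):
        voxels = np.argwhere(labels == lab)
        center = center_of_max_intensity(vol.data, voxels)
        peak = float(vol.data[tuple(voxels.T)].max())
        comps.append((peak, vol.voxel_to_world(center)[0]))
    comps.sort(key=lambda c: (-c[0], tuple(c[1])))
    return PointSet([Point(f"P{i + 1}", *xyz, "extracted", peak)
                     for i, (peak, xyz) in enumerate(comps)])


def burn_lines(vol: ImageVolume, trajectories: Iterable,
               s: BurnSettings | None = None) -> ImageVolume:
    """Print trajectories as high-intensity lines (entry-target segments).

    Voxels whose world centre lies within ``line_radius`` of a segment are
    set to ``marker_intensity`` x the original global max.  A trajectory
    endpoint outside the field of view raises a warning; the in-field part
    of the segment is still burned.
    """
    s = s or BurnSettings()
    out = vol.copy()
    trajectories = list(trajectories)
    if not trajectories:
        return out
    burn_val = s.marker_intensity * float(vol.data.max())
    for t in trajectories:
        a, b = np.asarray(t.entry, float), np.asarray(t.target, float)
        if not vol.contains_world(np.vstack([a, b])).all():
            warnings.warn(f"trajectory {t.name!r} endpoint outside field of "
                          "view; burning the in-field part only")
        sel = _segment_voxels(vol, a, b, s.line_radius)
        out.data[sel] = burn_val
    return out


def _segment_voxels(vol: ImageVolume, a: np.ndarray, b: np.ndarray,
                    radius: float):
    """Voxels whose world centre is within ``radius`` mm of segment a-b."""
    va = vol.world_to_voxel(a)[0]
    vb = vol.world_to_voxel(b)[0]
    pad = np.ceil(radius / vol.voxel_size).astype(int) + 1
    lo = np.maximum(np.floor(np.minimum(va, vb)).astype(int) - pad, 0)
    hi = np.minimum(np.ceil(np.maximum(va, vb)).astype(int) + pad + 1,
                    vol.shape)
    if np.any(lo >= hi):
        return tuple(np.empty(0, dtype=int) for _ in range(3))
    grid = np.stack(np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                                indexing="ij"), axis=-1).reshape(-1, 3)
    world = vol.voxel_to_world(grid)
    d = point_segment_distance(world, a, b)
    sel = grid[d <= radius]
    return sel[:, 0], sel[:, 1], sel[:, 2]


def point_segment_distance(points: np.ndarray, a: np.ndarray,
                           b: np.ndarray) -> np.ndarray:
    """Euclidean distance from each of (N, 3) points to segment a-b (mm)."""
    points = np.atleast_2d(points)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


# ---------------------------------------------------------------------------
# Point-set I/O (TSV and JSON)
# ---------------------------------------------------------------------------

_PS_COLUMNS = ["name", "x", "y", "z", "group", "value"]


def read_pointset(path: str | Path) -> PointSet:
    """Read a PointSet from TSV (name, x, y, z[, group, value]) or JSON."""
    path = Path(path)
    if path.suffix == ".json":
        rows = json.loads(path.read_text())
        if isinstance(rows, dict):
            rows = rows["points"]
    else:
        df = pd.read_csv(path, sep="\t")
        missing = {"name", "x", "y", "z"} - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        rows = df.to_dict("records")
    pts = []
    for r in rows:
        value = r.get("value")
        if value is not None and (isinstance(value, float) and np.isnan(value)):
            value = None
        group = r.get("group", "")
        if not isinstance(group, str) and (group is None or
                                           (isinstance(group, float)
                                            and np.isnan(group))):
            group = ""
        pts.append(Point(str(r["name"]), float(r["x"]), float(r["y"]),
                         float(r["z"]), str(group),
                         None if value is None else float(value)))
    return PointSet(pts)  # unique-name invariant enforced by constructor


def write_pointset(ps: PointSet, path: str | Path) -> None:
    """Write a PointSet as TSV or JSON (by extension); lossless round trip."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(
            {"points": [p._asdict() for p in ps.points]}, indent=1))
    else:
        ps.to_dataframe().to_csv(path, sep="\t", index=False)
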