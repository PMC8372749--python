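"""Subtraction ictal SPECT co-registered to MRI (SISCOM).

The standard normalize-subtract-z procedure: both perfusion volumes are
globally normalized to a mean of 100 within a brain mask, subtracted
(ictal - interictal), and the difference is expressed as voxelwise z-scores
against the masked difference distribution itself.  The resulting map is
thresholded (z >= 1.5 or 2 are the usual working thresholds) into
26-connected clusters for reporting.

Masking and any pre-smoothing are configurable because clinical practice
varies; the defaults here (Otsu brain mask from the base T1, no smoothing)
are assumptions, not prescriptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError, ValidationError
from .volumes_io import CONNECTIVITY_26, ImageVolume

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ZScoreMap:
    """Voxelwise ictal-interictal z-score map on the base grid.

    z is finite inside the brain mask and exactly 0 outside it.
    """

    z: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    threshold: float = 1.5

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.z.shape != self.mask.shape:
            raise ValidationError("z map and mask shapes differ")
        if not np.all(np.isfinite(self.z[self.mask])):
            raise ValidationError("z must be finite inside the mask")
        if np.any(self.z[~self.mask] != 0):
            raise ValidationError("z must be 0 outside the mask")

    def as_volume(self) -> ImageVolume:
        return ImageVolume(self.z, self.affine, "map", "base")


@dataclass
class Cluster:
    """One suprathreshold cluster of the z map."""

    voxel_count: int
    centroid: np.ndarray       # world mm
    peak_z: float
    peak_location: np.ndarray  # world mm
    voxels: np.ndarray = field(repr=False, default=None)  # (N, 3) indices


def default_brain_mask(t1: ImageVolume) -> ImageVolume:
    """Brain mask from the base T1: Otsu threshold, largest 26-connected
    component, hole filling."""
    thr = threshold_otsu(t1.data)
    fg = t1.data > thr
    labels, n = ndimage.label(fg, structure=CONNECTIVITY_26)
    if n == 0:
        raise DegenerateInputError("no foreground found for brain mask")
    sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    return ImageVolume(mask.astype(np.uint8), t1.affine.copy(), "mask",
                       t1.frame_id)


def _check_mask(vol: ImageVolume, mask: ImageVolume) -> np.ndarray:
    m = np.asarray(mask.data) > 0
    if m.shape != vol.data.shape:
        raise ValidationError("mask grid does not match volume grid")
    vals = np.unique(np.asarray(mask.data))
    if not np.all(np.isin(vals, (0, 1))):
        raise ValidationError("mask must be binary")
    return m


def normalize_perfusion(vol: ImageVolume, mask: ImageVolume) -> ImageVolume:
    """Scale a perfusion volume so its mean within the brain mask is 100."""
    m = _check_mask(vol, mask)
    mean = float(vol.data[m].mean()) if m.any() else 0.0
    if mean <= 0:
        raise ValidationError("mask mean must be > 0 for normalization")
    return vol.copy(data=vol.data * (100.0 / mean))


def compute_siscom(ictal: ImageVolume, interictal: ImageVolume,
                   mask: ImageVolume, smooth_fwhm: float = 0.0) -> ZScoreMap:
    """Ictal-interictal subtracted z-score image.

    d = normalize(ictal) - normalize(interictal); z = (d - mean_d) / sd_d
    with mean/sd taken over the brain mask; z clamped to 0 outside the mask.
    ``smooth_fwhm`` (mm) optionally Gaussian-smooths both normalized volumes
    before subtraction (0 = off).
    """
    if ictal.data.shape != interictal.data.shape or not np.allclose(
            ictal.affine, interictal.affine, atol=1e-6):
        raise ValidationError("ictal and interictal must share the base "
                              "grid; register and resample first")
    m = _check_mask(ictal, mask)
    a = normalize_perfusion(ictal, mask).data
    b = normalize_perfusion(interictal, mask).data
    if smooth_fwhm > 0:
        sigma_vox = smooth_fwhm * _FWHM_TO_SIGMA / ictal.voxel_size
        a = ndimage.gaussian_filter(a, sigma_vox)
        b = ndimage.gaussian_filter(b, sigma_vox)
    d = a - b
    sd = float(d[m].std())
    if sd == 0:
        raise DegenerateInputError(
            "zero variance in masked difference image (identical inputs?)")
    z = (d - float(d[m].mean())) / sd
    z[~m] = 0.0
    return ZScoreMap(z, ictal.affine.copy(), m)


def threshold_clusters(zm: ZScoreMap, z_thresh: float = 2.0,
                       min_voxels: int = 5) -> list[Cluster]:
    """26-connected clusters of z >= z_thresh with >= min_voxels voxels,
    sorted by peak z descending."""
    if z_thresh <= 0:
        raise ValidationError("z_thresh must be > 0")
    vol = ImageVolume(zm.z, zm.affine, "map")
    labels, n = ndimage.label(zm.z >= z_thresh, structure=CONNECTIVITY_26)
    clusters = []
    for lab in range(1, n + 1):
        voxels = np.argwhere(labels == lab)
        if len(voxels) < min_voxels:
            continue
        vals = zm.z[tuple(voxels.T)]
        peak_idx = voxels[int(np.argmax(vals))]
        clusters.append(Cluster(
            voxel_count=len(voxels),
            centroid=vol.voxel_to_world(voxels.mean(axis=0))[0],
            peak_z=float(vals.max()),
            peak_location=vol.voxel_to_world(peak_idx.astype(float))[0],
            voxels=voxels))
    clusters.sort(key=lambda c: (-c.peak_z, tuple(c.centroid)))
    return clusters


def clusters_to_table(clusters: list[Cluster]) -> pd.DataFrame:
    """Rank / voxel count / centroid / peak table for reporting."""
    rows = [{
        "rank": i + 1, "voxels": c.voxel_count,
        "centroid_x": c.centroid[0], "centroid_y": c.centroid[1],
        "centroid_z": c.centroid[2], "peak_z": c.peak_z,
        "peak_x": c.peak_location[0], "peak_y": c.peak_location[1],
        "peak_z_mm": c.peak_location[2],
    } for i, c in enumerate(clusters)]
    return pd.DataFrame(rows, columns=[
        "rank", "voxels", "centroid_x", "centroid_y", "centroid_z",
        "peak_z", "peak_x", "peak_y", "peak_z_mm"])
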