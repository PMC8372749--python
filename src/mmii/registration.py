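"""Rigid co-registration to the T1 base volume by mutual-information
maximization, resampling onto the base grid, and carrier-transform transfer
of derived statistical maps.

Every modality is registered *directly* to the base T1 with a 6-DOF rigid
transform that maximizes the mutual information (MI) between the joint
intensity histograms; transform composition is available when a chain
through an intermediate volume is preferred.  A statistical map (SISCOM z,
fMRI activation, morphometric z-map) that is voxel-aligned with a carrier
anatomical volume is never re-registered: the carrier's transformation
matrix is applied to the map unchanged (:func:`transfer_map`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import RegistrationError, ValidationError
from .volumes_io import ImageVolume, RigidTransform

_RAS2LPS = np.diag([-1.0, -1.0, 1.0, 1.0])


# ---------------------------------------------------------------------------
# Mutual information (joint-histogram, in bits)
# ---------------------------------------------------------------------------

def mutual_information(a: ImageVolume | np.ndarray,
                       b: ImageVolume | np.ndarray,
                       bins: int = 32,
                       winsorize: tuple[float, float] = (0.5, 99.5)) -> float:
    """MI(a, b) = H(a) + H(b) - H(a, b) in bits, from a bins x bins joint
    histogram of two volumes sampled on a common grid.

    Intensities are winsorized at the given percentiles before binning, for
    robustness to CT metal and MRI bias-field tails.  A constant image has
    zero entropy, hence MI = 0.
    """
    if bins < 2:
        raise ValidationError("bins must be >= 2")
    xa = (a.data if isinstance(a, ImageVolume) else np.asarray(a)).ravel()
    xb = (b.data if isinstance(b, ImageVolume) else np.asarray(b)).ravel()
    if xa.shape != xb.shape:
        raise ValidationError("volumes must share a common grid; resample "
                              "first")
    xa = np.clip(xa, *np.percentile(xa, winsorize))
    xb = np.clip(xb, *np.percentile(xb, winsorize))
    hist, _, _ = np.histogram2d(xa, xb, bins=bins)
    pxy = hist / hist.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)

    def entropy(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    mi = entropy(px) + entropy(py) - entropy(pxy.ravel())
    return max(mi, 0.0)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(vol: ImageVolume, t: RigidTransform, reference: ImageVolume,
             interp: str = "linear") -> ImageVolume:
    """Resample ``vol`` onto the grid of ``reference`` through rigid ``t``.

    ``t`` maps moving-volume world coordinates to reference (fixed) world
    coordinates.  Out-of-field voxels are set to 0.  Use ``interp="nearest"``
    for masks and label volumes.
    """
    if interp not in ("linear", "nearest"):
        raise ValidationError(f"unknown interpolation {interp!r}")
    order = 1 if interp == "linear" else 0
    # reference voxel -> reference world -> moving world -> moving voxel
    vox_map = (np.linalg.inv(vol.affine) @ np.linalg.inv(t.matrix)
               @ reference.affine)
    out = ndimage.affine_transform(
        np.asarray(vol.data, dtype=float), vox_map[:3, :3], vox_map[:3, 3],
        output_shape=reference.shape, order=order, mode="constant", cval=0.0,
        prefilter=False)
    return ImageVolume(out, reference.affine.copy(), vol.modality,
                       reference.frame_id)


def transfer_map(carrier_transform: RigidTransform, derived: ImageVolume,
                 reference: ImageVolume,
                 carrier: ImageVolume | None = None,
                 interp: str = "linear") -> ImageVolume:
    """Move a derived statistical map to the base frame using *exactly* the
    carrier volume's transformation matrix — no re-estimation.

    The map must be voxel-aligned with the carrier anatomical volume the
    transform was estimated on; pass ``carrier`` to have that checked.
    """
    if carrier is not None:
        if derived.shape != carrier.shape or not np.allclose(
                derived.affine, carrier.affine, atol=1e-6):
            raise ValidationError(
                "derived map is not voxel-aligned with its carrier volume")
    return resample(derived, carrier_transform, reference, interp=interp)


# ---------------------------------------------------------------------------
# Rigid registration
# ---------------------------------------------------------------------------

@dataclass
class RegistrationOptions:
    """Two-stage MI registration settings.

    Stage 1 is a coarse multi-resolution Mattes-MI gradient descent over
    the ``shrink_factors`` pyramid (regular-grid metric sampling, so the
    stage is deterministic for fixed inputs and options).  Stage 2 polishes
    the six rigid parameters at full resolution by derivative-free
    (Powell) maximization of the joint-histogram MI — bounded by
    ``polish_maxfev`` metric evaluations; set 0 to disable and extend the
    pyramid to full resolution instead (``shrink_factors=(4, 2, 1)``).

    ``mask_zero_fixed`` excludes zero-intensity fixed voxels from the
    metric — used for post-operative MRI where the resection cavity should
    not drive the alignment.
    """

    bins: int = 32
    shrink_factors: tuple[int, ...] = (4, 2)
    iterations: int = 100
    learning_rate: float = 1.0
    convergence_min: float = 1e-6
    convergence_window: int = 5
    sampling_fraction: float = 0.5  # regular grid sampling; deterministic
    seed: int = 12345
    mask_zero_fixed: bool = False
    polish_maxfev: int = 200
    polish_xtol: float = 1e-3
    polish_bins: int = 48


@dataclass
class RegistrationResult:
    """Outcome of a rigid registration.

    ``transform`` maps moving-volume world mm to fixed-volume world mm;
    ``metric_before``/``metric_after`` are joint-histogram MI in bits at the
    identity initialization and at the returned transform.
    """

    transform: RigidTransform
    metric_before: float
    metric_after: float
    iterations: int
    converged: bool

    def __post_init__(self) -> None:
        if self.metric_after < self.metric_before - 1e-9:
            raise ValidationError(
                "registration result decreased mutual information")


def _to_sitk(vol: ImageVolume) -> sitk.Image:
    """ImageVolume (RAS) -> SimpleITK image (LPS), preserving geometry."""
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.transpose(vol.data, (2, 1, 0)),
                             dtype=np.float64))
    aff = _RAS2LPS @ vol.affine
    spacing = np.linalg.norm(aff[:3, :3], axis=0)
    direction = aff[:3, :3] / spacing
    img.SetSpacing([float(s) for s in spacing])
    img.SetOrigin([float(v) for v in aff[:3, 3]])
    img.SetDirection([float(v) for v in direction.ravel()])
    return img


def _fov_overlap(moving: ImageVolume, fixed: ImageVolume) -> bool:
    corners = np.array(np.meshgrid(*[[0, n - 1] for n in moving.shape],
                                   indexing="ij")).reshape(3, -1).T
    world = moving.voxel_to_world(corners)
    lo, hi = world.min(axis=0), world.max(axis=0)
    fc = fixed.voxel_to_world(np.array(np.meshgrid(
        *[[0, n - 1] for n in fixed.shape], indexing="ij")).reshape(3, -1).T)
    flo, fhi = fc.min(axis=0), fc.max(axis=0)
    return bool(np.all(hi >= flo) and np.all(lo <= fhi))


def register_rigid(moving: ImageVolume, fixed: ImageVolume,
                   opts: RegistrationOptions | None = None
                   ) -> RegistrationResult:
    """Estimate the 6-DOF rigid transform (moving world -> fixed world) that
    maximizes mutual information, by multi-resolution optimization.

    Deterministic for fixed inputs and options.  If the optimizer fails to
    improve on the identity initialization, the identity transform is
    returned with ``converged=False``.
    """
    opts = opts or RegistrationOptions()
    if not _fov_overlap(moving, fixed):
        raise RegistrationError("moving and fixed fields of view do not "
                                "overlap at initialization")

    f_img = _to_sitk(fixed)
    m_img = _to_sitk(moving)

    initial = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(
        numberOfHistogramBins=opts.bins)
    if opts.sampling_fraction >= 1.0:
        reg.SetMetricSamplingStrategy(reg.NONE)
    else:
        reg.SetMetricSamplingStrategy(reg.REGULAR)
        reg.SetMetricSamplingPercentage(opts.sampling_fraction, opts.seed)
    if opts.mask_zero_fixed:
        mask = sitk.Cast(f_img != 0, sitk.sitkUInt8)
        reg.SetMetricFixedMask(mask)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsGradientDescentLineSearch(
        learningRate=opts.learning_rate,
        numberOfIterations=opts.iterations,
        convergenceMinimumValue=opts.convergence_min,
        convergenceWindowSize=opts.convergence_window)
    reg.SetOptimizerScalesFromPhysicalShift()
    shrink = list(opts.shrink_factors)
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel(
        [int(np.log2(s)) for s in shrink])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(initial, inPlace=False)

    try:
        final = reg.Execute(f_img, m_img)
        iterations = int(reg.GetOptimizerIteration())
        stop = reg.GetOptimizerStopConditionDescription()
        transform = _sitk_to_world_transform(final)
    except RuntimeError as exc:
        if "overlap" in str(exc):
            # the optimizer wandered out of the field of view mid-run;
            # report non-convergence from the identity start
            transform = RigidTransform.identity()
            iterations, stop = 0, "diverged out of field of view"
        else:
            raise RegistrationError(f"optimizer failure: {exc}") from exc

    if opts.polish_maxfev > 0:
        transform = _polish_full_resolution(moving, fixed, transform, opts)
    # Accept the estimate only if it does not lose MI vs. the identity
    # start; this guards against divergence on hard inputs.
    mi_before = mutual_information(
        resample(moving, RigidTransform.identity(), fixed).data,
        fixed.data, bins=opts.bins)
    mi_after = mutual_information(
        resample(moving, transform, fixed).data, fixed.data, bins=opts.bins)
    converged = ("Maximum number of iterations" not in stop
                 and "diverged" not in stop)
    if mi_after < mi_before:
        transform = RigidTransform.identity()
        mi_after = mi_before
        converged = False
    return RegistrationResult(transform, mi_before, mi_after, iterations,
                              converged)


def _polish_full_resolution(moving: ImageVolume, fixed: ImageVolume,
                            start: RigidTransform,
                            opts: RegistrationOptions) -> RigidTransform:
    """Derivative-free full-resolution refinement of the six rigid
    parameters (Euler degrees + mm, composed left of ``start``) by Powell
    maximization of the joint-histogram MI.  Deterministic."""
    from scipy.optimize import minimize

    fixed_data = np.asarray(fixed.data, dtype=float)
    sel = fixed_data != 0 if opts.mask_zero_fixed else slice(None)
    center = fixed.voxel_to_world((np.array(fixed.shape) - 1) / 2.0)[0]

    def to_transform(p: np.ndarray) -> RigidTransform:
        return RigidTransform.from_params(*p[:3], *p[3:],
                                          center=center).compose(start)

    def cost(p: np.ndarray) -> float:
        moved = resample(moving, to_transform(p), fixed).data
        return -mutual_information(moved[sel], fixed_data[sel],
                                   bins=opts.polish_bins)

    res = minimize(cost, np.zeros(6), method="Powell",
                   options=dict(xtol=opts.polish_xtol, ftol=1e-7,
                                maxfev=opts.polish_maxfev))
    return to_transform(res.x)


def _sitk_to_world_transform(t: sitk.Transform) -> RigidTransform:
    """Convert SimpleITK's fixed->moving LPS resampling transform into the
    moving->fixed RAS world mapping the toolkit stores."""
    t = sitk.Euler3DTransform(t.GetNthTransform(0) if isinstance(
        t, sitk.CompositeTransform) else t)
    R = np.array(t.GetMatrix()).reshape(3, 3)
    c = np.array(t.GetCenter())
    off = np.array(t.GetTranslation())
    m_lps = np.eye(4)
    m_lps[:3, :3] = R
    m_lps[:3, 3] = off + c - R @ c
    # fixed->moving in LPS; invert and change basis to RAS
    m_ras = _RAS2LPS @ np.linalg.inv(m_lps) @ _RAS2LPS
    # re-orthonormalize against float drift
    u, _, vt = np.linalg.svd(m_ras[:3, :3])
    m_ras[:3, :3] = u @ vt
    return RigidTransform(m_ras)
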