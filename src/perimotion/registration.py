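"""Phase-to-reference deformable registration and region propagation.

Each of the nine phase volumes is aligned to the 50% reference phase with a
diffeomorphic registration. The stored displacement field ``u`` lives on the
reference grid and maps reference-phase coordinates to phase-t coordinates
(``phi_t(x) = x + u(x)``), which is the direction needed to transport
reference-phase tissue points forward to every phase.

The default backend is a multi-resolution diffeomorphic-demons scheme with
Gaussian field smoothing, built on SimpleITK. Any callable satisfying the
backend contract (fixed image, moving image -> SimpleITK displacement-field
image mapping fixed to moving coordinates) can be plugged in instead, e.g. a
SyN implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import SimpleITK as sitk

from .errors import EmptyRegionError, RegistrationQualityError
from .io import BinaryMask, PhaseSeries

#: fraction of (foreground) voxels allowed to have a nonpositive Jacobian
#: determinant before a field is rejected as folded
JACOBIAN_TOLERANCE = 0.01


@dataclass
class DisplacementField:
    """Dense displacement field (mm) on the reference grid.

    ``vectors`` has shape ``(nx, ny, nz, 3)``; component order matches world
    axes. The field realizes the reference-to-phase mapping phi_t.
    """

    vectors: np.ndarray
    affine: np.ndarray
    phase_percent: int

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(f"field must have shape (nx, ny, nz, 3), got {self.vectors.shape}")
        if not np.all(np.isfinite(self.vectors)):
            raise RegistrationQualityError("displacement field contains non-finite values")

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)


# ---------------------------------------------------------------------------
# numpy <-> SimpleITK bridging (axis-aligned affines)


def _affine_to_sitk_params(affine: np.ndarray):
    rot = affine[:3, :3]
    spacing = np.linalg.norm(rot, axis=0)
    direction = rot / spacing
    origin = affine[:3, 3]
    return spacing, direction, origin


def volume_to_sitk(voxels: np.ndarray, affine: np.ndarray) -> sitk.Image:
    """Wrap an (i, j, k)-indexed array as a SimpleITK image in world mm."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(voxels, (2, 1, 0))))
    spacing, direction, origin = _affine_to_sitk_params(affine)
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetDirection(tuple(direction.flatten()))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def sitk_to_array(img: sitk.Image) -> np.ndarray:
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim == 4:  # vector image: (z, y, x, c) -> (x, y, z, c)
        return np.transpose(arr, (2, 1, 0, 3))
    return np.transpose(arr, (2, 1, 0))


def field_to_sitk(field: DisplacementField) -> sitk.Image:
    arr = np.ascontiguousarray(
        np.transpose(field.vectors, (2, 1, 0, 3)).astype(np.float64)
    )
    img = sitk.GetImageFromArray(arr, isVector=True)
    spacing, direction, origin = _affine_to_sitk_params(field.affine)
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetDirection(tuple(direction.flatten()))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


# ---------------------------------------------------------------------------
# demons backend


class DemonsBackend:
    """Multi-resolution diffeomorphic demons with Gaussian field smoothing.

    Parameters
    ----------
    shrink_factors:
        Pyramid shrink factor per level, coarse to fine (1 = full resolution).
    smoothing_sigmas:
        Image smoothing (voxels at full resolution) applied per level before
        registration.
    iterations:
        Demons iterations per level.
    field_sigma:
        Standard deviation (voxels) of the Gaussian regularization applied to
        the displacement field each iteration.
    """

    def __init__(
        self,
        shrink_factors: Sequence[int] = (4, 2),
        smoothing_sigmas: Sequence[float] = (3.0, 1.0),
        iterations: Sequence[int] = (60, 30),
        field_sigma: float = 1.0,
        intensity_difference_threshold: float = 0.001,
    ) -> None:
        if not len(shrink_factors) == len(smoothing_sigmas) == len(iterations):
            raise ValueError("per-level parameter lists must have equal length")
        self.shrink_factors = list(shrink_factors)
        self.smoothing_sigmas = list(smoothing_sigmas)
        self.iterations = list(iterations)
        self.field_sigma = field_sigma
        self.intensity_difference_threshold = intensity_difference_threshold

    def _filter(self, n_iter: int) -> sitk.DiffeomorphicDemonsRegistrationFilter:
        f = sitk.DiffeomorphicDemonsRegistrationFilter()
        f.SetNumberOfIterations(int(n_iter))
        f.SetSmoothDisplacementField(True)
        f.SetStandardDeviations(self.field_sigma)
        f.SetIntensityDifferenceThreshold(self.intensity_difference_threshold)
        return f

    @staticmethod
    def _shrink(img: sitk.Image, factor: int, sigma_vox: float) -> sitk.Image:
        if sigma_vox > 0:
            smoothed = sitk.SmoothingRecursiveGaussian(
                img, sigma_vox * min(img.GetSpacing())
            )
        else:
            smoothed = img
        if factor == 1:
            return smoothed
        return sitk.Shrink(smoothed, [int(factor)] * img.GetDimension())

    def __call__(self, fixed: sitk.Image, moving: sitk.Image) -> sitk.Image:
        fixed = sitk.Cast(fixed, sitk.sitkFloat32)
        moving = sitk.Cast(moving, sitk.sitkFloat32)
        field: sitk.Image | None = None
        for factor, sigma, n_iter in zip(
            self.shrink_factors, self.smoothing_sigmas, self.iterations
        ):
            f_lvl = self._shrink(fixed, factor, sigma)
            m_lvl = self._shrink(moving, factor, sigma)
            demons = self._filter(n_iter)
            if field is None:
                field = demons.Execute(f_lvl, m_lvl)
            else:
                field = demons.Execute(
                    f_lvl,
                    m_lvl,
                    sitk.Resample(
                        field,
                        f_lvl,
                        sitk.Transform(),
                        sitk.sitkLinear,
                        0.0,
                        sitk.sitkVectorFloat64,
                    ),
                )
        assert field is not None
        if tuple(field.GetSize()) != tuple(fixed.GetSize()):
            field = sitk.Resample(
                field, fixed, sitk.Transform(), sitk.sitkLinear, 0.0, sitk.sitkVectorFloat64
            )
        return field


Backend = Callable[[sitk.Image, sitk.Image], sitk.Image]


# ---------------------------------------------------------------------------
# registration driver


def jacobian_nonpositive_fraction(
    field: DisplacementField, foreground: np.ndarray | None = None
) -> float:
    """Fraction of (foreground) voxels where det(J(identity + u)) <= 0."""
    jac = sitk_to_array(sitk.DisplacementFieldJacobianDeterminant(field_to_sitk(field)))
    if foreground is not None:
        jac = jac[foreground]
    if jac.size == 0:
        return 0.0
    return float((jac <= 0).mean())


def register_to_reference(
    series: PhaseSeries,
    backend: Backend | None = None,
    foreground: np.ndarray | None = None,
    jacobian_tolerance: float = JACOBIAN_TOLERANCE,
) -> list[DisplacementField]:
    """Register every phase to the 50% reference phase.

    Returns one :class:`DisplacementField` per phase in series order; the
    field at the reference phase is identically zero. Each field maps
    reference coordinates to phase-t coordinates. Fields whose Jacobian
    determinant is nonpositive on more than ``jacobian_tolerance`` of the
    (foreground) voxels are rejected.
    """
    backend = backend or DemonsBackend()
    affine = series.affine
    fixed_img = volume_to_sitk(series.reference.voxels, affine)
    fields: list[DisplacementField] = []
    for k, vol in enumerate(series.volumes):
        if k == series.ref_index:
            vectors = np.zeros(series.shape + (3,), dtype=np.float32)
        else:
            moving_img = volume_to_sitk(vol.voxels, affine)
            try:
                field_img = backend(fixed_img, moving_img)
            except Exception as exc:  # backend contract violation
                raise RegistrationQualityError(
                    f"registration backend failed at phase {vol.phase_percent}%: {exc}"
                ) from exc
            vectors = sitk_to_array(field_img).astype(np.float32)
        fld = DisplacementField(vectors=vectors, affine=affine, phase_percent=vol.phase_percent)
        frac = jacobian_nonpositive_fraction(fld, foreground)
        if frac > jacobian_tolerance:
            raise RegistrationQualityError(
                f"field at phase {vol.phase_percent}% folds on {frac:.1%} of voxels "
                f"(tolerance {jacobian_tolerance:.1%})"
            )
        fields.append(fld)
    return fields


def invert_field(field: DisplacementField, n_iterations: int = 50) -> DisplacementField:
    """Invert a displacement field by fixed-point iteration (SimpleITK)."""
    inv_img = sitk.InvertDisplacementField(
        field_to_sitk(field),
        maximumNumberOfIterations=n_iterations,
        maxErrorToleranceThreshold=0.05 * float(min(np.linalg.norm(field.affine[:3, :3], axis=0))),
        meanErrorToleranceThreshold=0.001,
        enforceBoundaryCondition=True,
    )
    return DisplacementField(
        vectors=sitk_to_array(inv_img).astype(np.float32),
        affine=field.affine,
        phase_percent=field.phase_percent,
    )


def propagate_region(mask_ref: BinaryMask, field: DisplacementField) -> BinaryMask:
    """Deform a reference-grid region through phi_t.

    The deformed region is ``phi_t(Omega_ref)`` rasterized on the reference
    grid (it inherits the reference spatial resolution): a voxel x belongs to
    the output when ``phi_t^{-1}(x)`` falls inside the input mask, so the
    field is inverted once and the mask resampled with nearest-neighbour
    interpolation.
    """
    if mask_ref.n_voxels == 0:
        raise EmptyRegionError("cannot propagate an empty region")
    if np.allclose(field.vectors, 0.0):
        return BinaryMask(voxels=mask_ref.voxels.copy(), affine=mask_ref.affine, label=mask_ref.label)
    inv = invert_field(field)
    tx = sitk.DisplacementFieldTransform(field_to_sitk(inv))
    mask_img = volume_to_sitk(mask_ref.voxels.astype(np.uint8), mask_ref.affine)
    out = sitk.Resample(mask_img, mask_img, tx, sitk.sitkNearestNeighbor, 0)
    return BinaryMask(voxels=sitk_to_array(out) > 0, affine=mask_ref.affine, label=mask_ref.label)


def mask_boundary_shell(mask: BinaryMask) -> BinaryMask:
    """One-voxel boundary shell of a filled region (the membrane surface).

    The pericardial input mask is the filled sac; tissue motion of the
    pericardium itself is tracked on this shell.
    """
    from scipy import ndimage

    if mask.n_voxels == 0:
        raise EmptyRegionError("empty mask has no boundary")
    eroded = ndimage.binary_erosion(mask.voxels, ndimage.generate_binary_structure(3, 1))
    return BinaryMask(voxels=mask.voxels & ~eroded, affine=mask.affine, label=mask.label)


def save_field(field: DisplacementField, path) -> None:
    """Store a displacement field as 4D NIfTI (vector dimension last, mm)."""
    import nibabel as nib

    nib.save(nib.Nifti1Image(field.vectors.astype(np.float32), field.affine), str(path))


def load_field(path, phase_percent: int = 0) -> DisplacementField:
    import nibabel as nib

    img = nib.load(str(path))
    return DisplacementField(
        vectors=np.asarray(img.get_fdata(dtype=np.float32)),
        affine=img.affine,
        phase_percent=phase_percent,
    )
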