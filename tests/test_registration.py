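"""Deformable registration backend, field handling and region propagation."""

import numpy as np
import pytest
import SimpleITK as sitk

from perimotion.io import BinaryMask, CTVolume, PhaseSeries, EXPECTED_PHASES
from perimotion.errors import EmptyRegionError, RegistrationQualityError
from perimotion.motion import build_trajectories, sample_field_at_points
from perimotion.registration import (
    DemonsBackend,
    DisplacementField,
    field_to_sitk,
    invert_field,
    jacobian_nonpositive_fraction,
    propagate_region,
    register_to_reference,
    sitk_to_array,
    volume_to_sitk,
)

from conftest import make_blob_volume

SPACING = 2.0


def _series_from_volumes(ref, others):
    """Build a nine-phase series with `ref` at 50% and `others` cycled in."""
    volumes = []
    j = 0
    for p in EXPECTED_PHASES:
        if p == 50:
            v = ref
        else:
            v = others[j % len(others)]
            j += 1
        volumes.append(CTVolume(voxels=v.voxels, affine=v.affine, phase_percent=p))
    return PhaseSeries(volumes=volumes, ref_index=4)


def _textured_blob(seed=0, shape=(32, 32, 32), shift_mm=(0.0, 0.0, 0.0)):
    """Blob plus smooth texture so the interior is trackable."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    base = make_blob_volume(shape=shape, spacing=SPACING, radius=18.0,
                            center=np.asarray(shape) * SPACING / 2.0 + np.asarray(shift_mm))
    tex = gaussian_filter(rng.standard_normal(shape), 2.0)
    tex = 30.0 * tex / tex.std()
    # texture is world-anchored: sample it at the shifted coordinates
    if any(shift_mm):
        from scipy.ndimage import shift as ndshift

        tex = ndshift(tex, np.asarray(shift_mm) / SPACING, order=1, mode="nearest")
    vox = base.voxels + tex * (base.voxels > 20)
    return CTVolume(voxels=vox.astype(np.float32), affine=base.affine, phase_percent=50)


class TestSitkBridge:
    def test_volume_round_trip(self):
        vol = make_blob_volume()
        img = volume_to_sitk(vol.voxels, vol.affine)
        np.testing.assert_array_equal(sitk_to_array(img), vol.voxels)
        # world coordinate of voxel (i, j, k) agrees with the affine
        idx = (3, 7, 11)
        np.testing.assert_allclose(
            img.TransformIndexToPhysicalPoint(idx),
            (vol.affine[:3, :3] @ idx + vol.affine[:3, 3]),
            atol=1e-6,
        )

    def test_field_round_trip(self):
        rng = np.random.default_rng(0)
        field = DisplacementField(
            vectors=rng.normal(size=(8, 9, 10, 3)), affine=np.diag([2.0, 2.0, 2.0, 1.0]),
            phase_percent=10,
        )
        back = sitk_to_array(field_to_sitk(field))
        np.testing.assert_allclose(back, field.vectors, atol=1e-12)


class TestRegistration:
    def test_identity_registration_is_near_zero(self):
        vol = _textured_blob()
        series = _series_from_volumes(vol, [vol])
        fields = register_to_reference(series, DemonsBackend(iterations=(20, 10)))
        fg = vol.voxels > 20
        for fld in fields:
            assert fld.magnitude[fg].max() <= 0.1 * SPACING

    def test_translation_recovered_within_half_mm(self):
        fixed = _textured_blob(seed=1)
        moving = _textured_blob(seed=1, shift_mm=(3.0, 0.0, 0.0))
        series = _series_from_volumes(fixed, [moving])
        fields = register_to_reference(series)
        fg = fixed.voxels > 40
        # erode so the check sits inside the object, not on its rim
        from scipy.ndimage import binary_erosion

        fg = binary_erosion(fg, iterations=2)
        for k, fld in enumerate(fields):
            if k == series.ref_index:
                continue
            mean_vec = fld.vectors[fg].mean(axis=0)
            np.testing.assert_allclose(mean_vec, [3.0, 0.0, 0.0], atol=0.5)

    def test_mean_endpoint_error_below_half_mm(self):
        fixed = _textured_blob(seed=2)
        moving = _textured_blob(seed=2, shift_mm=(2.0, -1.5, 1.0))
        series = _series_from_volumes(fixed, [moving])
        fields = register_to_reference(series)
        fg = np.argwhere(fixed.voxels > 40)[::7] * SPACING
        k = 0  # any non-reference phase
        rec = sample_field_at_points(fields[k].vectors, fields[k].affine, fg.astype(float))
        epe = np.linalg.norm(rec - np.array([2.0, -1.5, 1.0]), axis=1)
        assert epe.mean() <= 0.5

    def test_folded_field_rejected(self):
        vol = make_blob_volume(spacing=SPACING)

        def folding_backend(fixed, moving):
            shape = vol.voxels.shape
            vec = np.zeros(shape + (3,))
            vec[..., 0] = -3.0 * SPACING * np.sin(
                np.arange(shape[0])[:, None, None] * np.pi / 2.0
            )  # alternating compression: negative Jacobian on many voxels
            return field_to_sitk(
                DisplacementField(vectors=vec, affine=vol.affine, phase_percent=0)
            )

        series = _series_from_volumes(vol, [vol])
        with pytest.raises(RegistrationQualityError, match="folds"):
            register_to_reference(series, folding_backend)

    def test_backend_failure_wrapped(self):
        vol = make_blob_volume(spacing=SPACING)
        series = _series_from_volumes(vol, [vol])

        def broken(fixed, moving):
            raise RuntimeError("boom")

        with pytest.raises(RegistrationQualityError, match="backend failed"):
            register_to_reference(series, broken)


class TestJacobian:
    def test_identity_field_has_unit_jacobian(self):
        field = DisplacementField(
            vectors=np.zeros((10, 10, 10, 3)), affine=np.diag([2.0, 2.0, 2.0, 1.0]),
            phase_percent=50,
        )
        assert jacobian_nonpositive_fraction(field) == 0.0

    def test_strong_compression_detected(self):
        shape = (16, 16, 16)
        vec = np.zeros(shape + (3,))
        # x -> -x about the center: Jacobian -1 everywhere
        xs = (np.arange(shape[0]) - 7.5) * 2.0
        vec[..., 0] = -2.0 * xs[:, None, None]
        field = DisplacementField(vectors=vec, affine=np.diag([2.0, 2.0, 2.0, 1.0]), phase_percent=0)
        assert jacobian_nonpositive_fraction(field) > 0.5


class TestPropagation:
    @staticmethod
    def _ball_mask(shape=(32, 32, 32), radius=8.0, center=None):
        if center is None:
            center = np.asarray(shape) * SPACING / 2.0
        idx = np.indices(shape).astype(float) * SPACING
        r = np.sqrt(sum((idx[i] - center[i]) ** 2 for i in range(3)))
        return BinaryMask(voxels=r <= radius, affine=np.diag([SPACING] * 3 + [1.0]))

    def test_identity_field_returns_input(self):
        mask = self._ball_mask()
        field = DisplacementField(
            vectors=np.zeros(mask.voxels.shape + (3,)), affine=mask.affine, phase_percent=50
        )
        out = propagate_region(mask, field)
        np.testing.assert_array_equal(out.voxels, mask.voxels)

    def test_translation_moves_centroid(self):
        mask = self._ball_mask()
        vec = np.zeros(mask.voxels.shape + (3,))
        vec[..., 0] = 5.0
        field = DisplacementField(vectors=vec, affine=mask.affine, phase_percent=10)
        out = propagate_region(mask, field)
        shift = out.point_coordinates().mean(axis=0) - mask.point_coordinates().mean(axis=0)
        np.testing.assert_allclose(shift, [5.0, 0.0, 0.0], atol=SPACING / 2)

    def test_isotropic_expansion_scales_volume(self):
        # 1 mm grid so nearest-neighbour rasterization noise stays below the
        # 5% band around the continuum volume ratio 1.1^3
        shape = (48, 48, 48)
        affine = np.eye(4)
        center = np.asarray(shape) / 2.0
        idx = np.indices(shape).astype(float)
        r = np.sqrt(sum((idx[i] - center[i]) ** 2 for i in range(3)))
        mask = BinaryMask(voxels=r <= 12.0, affine=affine)
        vec = np.stack([0.1 * (idx[i] - center[i]) for i in range(3)], axis=-1)
        field = DisplacementField(vectors=vec, affine=affine, phase_percent=10)
        out = propagate_region(mask, field)
        ratio = out.n_voxels / mask.n_voxels
        assert ratio == pytest.approx(1.1**3, rel=0.05)

    def test_empty_mask_rejected(self):
        mask = BinaryMask(voxels=np.zeros((8, 8, 8), bool), affine=np.diag([SPACING] * 3 + [1.0]))
        field = DisplacementField(vectors=np.zeros((8, 8, 8, 3)), affine=mask.affine, phase_percent=10)
        with pytest.raises(EmptyRegionError):
            propagate_region(mask, field)

    def test_inversion_accuracy(self):
        mask = self._ball_mask()
        vec = np.zeros(mask.voxels.shape + (3,))
        vec[..., 1] = 4.0
        field = DisplacementField(vectors=vec, affine=mask.affine, phase_percent=10)
        inv = invert_field(field)
        interior = np.s_[4:-4, 4:-4, 4:-4]
        np.testing.assert_allclose(inv.vectors[interior][..., 1], -4.0, atol=0.1)


class TestTrajectories:
    def test_zero_fields_give_constant_positions(self):
        affine = np.diag([SPACING] * 3 + [1.0])
        fields = [
            DisplacementField(vectors=np.zeros((8, 8, 8, 3)), affine=affine, phase_percent=p)
            for p in EXPECTED_PHASES
        ]
        pts = np.array([[4.0, 6.0, 8.0], [10.0, 10.0, 10.0]])
        traj = build_trajectories(fields, pts, tissue="EAT")
        assert traj.positions.shape == (9, 2, 3)
        for k in range(9):
            np.testing.assert_array_equal(traj.positions[k], pts)

    def test_constructed_linear_fields_give_linear_trajectories(self):
        affine = np.diag([SPACING] * 3 + [1.0])
        fields = []
        for k, p in enumerate(EXPECTED_PHASES):
            vec = np.zeros((8, 8, 8, 3))
            vec[..., 0] = 10.0 * k / 9.0
            fields.append(DisplacementField(vectors=vec, affine=affine, phase_percent=p))
        pts = np.array([[6.0, 6.0, 6.0]])
        traj = build_trajectories(fields, pts, tissue="EAT")
        np.testing.assert_allclose(traj.positions[:, 0, 0], 6.0 + 10.0 * np.arange(9) / 9.0)

    def test_single_point_has_nine_positions(self):
        affine = np.diag([SPACING] * 3 + [1.0])
        fields = [
            DisplacementField(vectors=np.zeros((8, 8, 8, 3)), affine=affine, phase_percent=p)
            for p in EXPECTED_PHASES
        ]
        traj = build_trajectories(fields, np.array([[1.0, 1.0, 1.0]]), tissue="pericardium")
        assert traj.positions.shape == (9, 1, 3)
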