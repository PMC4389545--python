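import numpy as np
import pytest
from scipy import ndimage

from agetpl.phantom import PhantomSpec, make_phantom
from agetpl.register import (
    AffineTransform,
    DeformationField,
    RegistrationError,
    ResolutionSchedule,
    apply_transform,
    composition_residual,
    invert_deformation,
    register_deformable,
    register_rigid,
    registration_metric,
)
from agetpl.volume import Volume


@pytest.fixture(scope="module")
def pair():
    a = make_phantom(PhantomSpec(age=25, seed=3, grid_shape=(48, 48, 48),
                                 shape_jitter=1.0, gm_slope=-0.0028,
                                 wm_curv=4e-5))
    b = make_phantom(PhantomSpec(age=80, seed=4, grid_shape=(48, 48, 48),
                                 shape_jitter=1.0, gm_slope=-0.0028,
                                 wm_curv=4e-5))
    return a, b


class TestSchedule:
    def test_parse(self):
        assert ResolutionSchedule.parse("50x50x0").iterations == (50, 50, 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ResolutionSchedule((50, -1, 0))


class TestRigid:
    def test_self_registration_identity(self, pair):
        fixed = pair[0].brain
        xf = register_rigid(fixed, fixed)
        assert np.abs(xf.matrix[:3, 3]).max() < 0.1
        angle = np.rad2deg(np.arccos(np.clip(
            (np.trace(xf.matrix[:3, :3]) - 1) / 2, -1, 1)))
        assert angle < 0.1

    def test_translation_recovered(self, pair):
        fixed = pair[0].brain
        moving = Volume(fixed.data.copy(), fixed.affine.copy())
        moving.affine[0, 3] += 3.0
        xf = register_rigid(moving, fixed)
        assert np.abs(xf.matrix[:3, 3] - [-3.0, 0, 0]).max() < 0.2

    def test_rotation_recovered(self, pair):
        fixed = pair[0].brain
        th = np.deg2rad(5)
        rot = np.eye(4)
        rot[:2, :2] = [[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]
        moving = Volume(fixed.data.copy(), rot @ fixed.affine)
        xf = register_rigid(moving, fixed)
        angle = np.rad2deg(np.arccos(np.clip(
            (np.trace(xf.matrix[:3, :3]) - 1) / 2, -1, 1)))
        assert angle == pytest.approx(5.0, abs=0.5)

    def test_constant_images_rejected(self):
        flat = Volume(np.zeros((8, 8, 8)), np.eye(4))
        with pytest.raises(RegistrationError):
            register_rigid(flat, flat)

    def test_rigid_preserves_world_distances(self, pair):
        fixed = pair[0].brain
        moving = Volume(fixed.data.copy(), fixed.affine.copy())
        moving.affine[1, 3] += 4.0
        xf = register_rigid(moving, fixed)
        rng = np.random.default_rng(0)
        pts = rng.uniform(-30, 30, size=(3, 20))
        moved = xf.matrix[:3, :3] @ pts + xf.matrix[:3, 3:4]
        d0 = np.linalg.norm(pts[:, :10] - pts[:, 10:], axis=0)
        d1 = np.linalg.norm(moved[:, :10] - moved[:, 10:], axis=0)
        assert np.allclose(d0, d1, rtol=1e-6)


class TestDeformable:
    def test_self_registration_near_zero_field(self, pair):
        fixed = pair[0].brain
        fld = register_deformable(fixed, fixed,
                                  schedule=ResolutionSchedule((10, 5, 5)))
        voxel = fixed.voxel_sizes.min()
        assert np.abs(fld.forward).max() < 0.1 * voxel

    def test_metric_improves_over_affine(self, pair):
        a, b = pair
        fld = register_deformable(a.brain, b.brain,
                                  schedule=ResolutionSchedule((15, 8, 4)))
        ssd_affine = registration_metric(a.brain, b.brain, fld.pre_affine)
        ssd_warp = registration_metric(a.brain, b.brain, fld)
        assert ssd_warp < ssd_affine

    def test_fine_schedule_beats_coarse(self, pair):
        a, b = pair
        coarse = register_deformable(a.brain, b.brain,
                                     schedule=ResolutionSchedule((10, 0, 0)))
        fine = register_deformable(a.brain, b.brain,
                                   schedule=ResolutionSchedule((10, 5, 3)))
        m_coarse = registration_metric(a.brain, b.brain, coarse)
        m_fine = registration_metric(a.brain, b.brain, fine)
        assert m_fine <= m_coarse

    def test_ventricle_alignment(self):
        # same subject except for the aging parameters: ventricle radii
        # differ by ~2 mm; after warping, equivalent radii agree to 0.5 mm
        a = make_phantom(PhantomSpec(age=40, seed=7, grid_shape=(48, 48, 48),
                                     gm_slope=-0.0028, wm_curv=4e-5))
        b = make_phantom(PhantomSpec(age=62, seed=7, grid_shape=(48, 48, 48),
                                     gm_slope=-0.0028, wm_curv=4e-5))
        fld = register_deformable(a.brain, b.brain,
                                  schedule=ResolutionSchedule((30, 20, 10)))
        vent_a = Volume(a.truth_pve.maps["om"], a.brain.affine)
        warped = apply_transform(vent_a, fld)
        vv = b.brain.voxel_volume
        r_warped = (3 * warped.data.sum() * vv / (4 * np.pi)) ** (1 / 3)
        r_b = (3 * b.truth_pve.maps["om"].sum() * vv / (4 * np.pi)) ** (1 / 3)
        assert abs(r_warped - r_b) < 0.5

    def test_inverse_residual_within_tolerance(self, pair):
        a, b = pair
        fld = register_deformable(a.brain, b.brain,
                                  schedule=ResolutionSchedule((15, 8, 4)))
        voxel = b.brain.voxel_sizes.min()
        assert composition_residual(fld) < 0.2 * voxel


class TestApplyTransform:
    def test_identity_affine_same_grid(self, pair):
        vol = pair[0].brain
        out = apply_transform(vol, AffineTransform.identity(), target_grid=vol)
        assert np.allclose(out.data, vol.data, atol=1e-9)

    def test_integer_voxel_translation_nearest(self, pair):
        vol = pair[0].brain
        m = np.eye(4)
        m[0, 3] = 2.0  # one voxel at 2 mm
        out = apply_transform(vol, AffineTransform(m), target_grid=vol,
                              interp="nearest")
        assert np.array_equal(out.data[1:], vol.data[:-1])

    def test_unknown_interp_rejected(self, pair):
        with pytest.raises(ValueError):
            apply_transform(pair[0].brain, AffineTransform.identity(),
                            target_grid=pair[0].brain, interp="cubic")

    def test_forward_then_inverse_roundtrip(self, pair):
        vol = pair[0].brain
        rng = np.random.default_rng(3)
        u = np.stack([ndimage.gaussian_filter(rng.standard_normal(vol.shape),
                                              5, mode="nearest")
                      for _ in range(3)])
        u *= 2.0 / np.abs(u).max()
        fld = DeformationField(u, np.zeros_like(u), AffineTransform.identity(),
                               vol.affine)
        fld = invert_deformation(fld)
        fld = invert_deformation(fld)  # double swap: back to the original side
        warped = apply_transform(vol, fld)
        back = apply_transform(warped, invert_deformation(fld), target_grid=vol)
        mad = np.abs(back.data - vol.data).mean()
        assert mad < 0.02 * np.ptp(vol.data)

    def test_pve_warp_renormalizes(self, pair):
        pve = pair[0].truth_pve
        m = np.eye(4)
        m[0, 3] = 1.0
        out = apply_transform(pve, AffineTransform(m),
                              target_grid=(pve.mask.shape, pve.affine))
        out.validate()


class TestInvertDeformation:
    def _field(self, u, affine):
        return DeformationField(u, np.zeros_like(u), AffineTransform.identity(),
                                affine)

    def test_zero_field_inverts_to_zero(self):
        u = np.zeros((3, 12, 12, 12))
        inv = invert_deformation(self._field(u, np.eye(4) * 2 - np.diag([0] * 3 + [1])))
        assert np.abs(inv.forward).max() == 0

    def test_constant_translation_exact(self):
        u = np.zeros((3, 12, 12, 12))
        u[1] = 1.5
        aff = np.eye(4)
        inv = invert_deformation(self._field(u, aff))
        assert np.allclose(inv.forward[1], -1.5, atol=1e-6)

    def test_smooth_field_residual(self, pair):
        from agetpl.register import _invert_displacement

        vol = pair[0].brain
        rng = np.random.default_rng(8)
        u = np.stack([ndimage.gaussian_filter(rng.standard_normal(vol.shape),
                                              5, mode="nearest")
                      for _ in range(3)])
        u *= 1.6 / np.abs(u).max()
        u_inv = _invert_displacement(u, vol.affine, vol.world_coordinates())
        fld = DeformationField(u, u_inv, AffineTransform.identity(), vol.affine)
        voxel = vol.voxel_sizes.min()
        assert composition_residual(fld) < 0.2 * voxel

    def test_nonconvergent_inverse_raises(self):
        # displacement folding space over itself has no fixed-point inverse
        u = np.zeros((3, 10, 10, 10))
        u[0] = np.linspace(8, -8, 10)[:, None, None]  # strong compression
        fld = self._field(u, np.eye(4))
        with pytest.raises(RegistrationError):
            invert_deformation(fld, max_iter=3)
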