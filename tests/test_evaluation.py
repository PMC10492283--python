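import numpy as np
import pytest

from maxstab.core_io import ImageVolume, LandmarkSet
from maxstab.evaluation import (CephImage, ReferenceFrame, Rigid2D, ToothDisplacement,
                                icc_sample_size, measure_tooth_displacement,
                                method_agreement, project_lateral, superimpose_2d)
from maxstab.registration import RigidTransform


class TestProjection:
    def test_single_bright_voxel_projects_to_its_yz_pixel(self):
        data = np.zeros((20, 22, 24), np.float32)
        data[15, 7, 9] = 100.0
        vol = ImageVolume(data, spacing=(0.5, 0.5, 0.5))
        ceph = project_lateral(vol, "right")
        assert ceph.data.shape == (22, 24)
        assert np.unravel_index(np.argmax(ceph.data), ceph.data.shape) == (7, 9)
        assert project_lateral(vol, "left").data.max() == 0.0

    def test_mirror_symmetric_volume_gives_equal_sides(self, rng):
        half = rng.random((10, 16, 16)).astype(np.float32)
        data = np.concatenate([half[::-1], half], axis=0)
        vol = ImageVolume(data, spacing=(0.5, 0.5, 0.5))
        np.testing.assert_allclose(project_lateral(vol, "left").data,
                                   project_lateral(vol, "right").data)

    def test_screws_visible_in_phantom_projection(self, small_baseline, small_spec):
        ceph = project_lateral(small_baseline.volume, "right")
        assert (ceph.data > 0.8 * small_spec.intensity_screw).any()

    def test_invalid_side_and_plane(self, small_baseline):
        with pytest.raises(ValueError, match="side"):
            project_lateral(small_baseline.volume, "up")
        with pytest.raises(ValueError, match="midsagittal"):
            project_lateral(small_baseline.volume, "left", midsagittal_index=99)


class TestSuperimpose2D:
    def _ceph(self, small_baseline):
        return project_lateral(small_baseline.volume, "right")

    def _ref(self, small_baseline):
        return project_lateral(small_baseline.mask, "right").data

    def test_identity_for_equal_images(self, small_baseline):
        ceph = self._ceph(small_baseline)
        T = superimpose_2d(ceph, ceph, self._ref(small_baseline))
        assert abs(T.angle_deg) < 0.05
        assert np.linalg.norm(T.translation) < 0.05

    def test_rigid_only_pair_2d_agrees_with_3d(self, rigid_only_pair):
        """On a growth-free pair, tooth displacements measured through the
        lateral-projection path match the 3D masked-registration path to
        within projection/interpolation error (< 0.5 voxel)."""
        from maxstab.superimposition import masked_rigid_register
        base, t2, gt = rigid_only_pair
        res3d = masked_rigid_register(base.volume, t2, base.mask)
        # landmark sets: T1 landmarks and their rigidly moved counterparts
        lms_t1 = base.landmarks
        lms_t2 = lms_t1.transformed(lambda p: gt.rigid.apply(p[None])[0])
        rec3d = measure_tooth_displacement(lms_t1, lms_t2, res3d.transform)
        for side, prefix in (("right", "R"), ("left", "L")):
            c1 = project_lateral(base.volume, side)
            c2 = project_lateral(t2, side)
            ref = project_lateral(base.mask, side)
            t2d = superimpose_2d(c1, c2, ref.data)
            rec2d = measure_tooth_displacement(lms_t1, lms_t2, t2d)
            for r2 in rec2d:
                if not r2.tooth.startswith(prefix):
                    continue
                r3 = next(r for r in rec3d if r.tooth == r2.tooth)
                assert abs(r2.x - r3.x) < 0.5 * base.volume.spacing[0]
                assert abs(r2.y - r3.y) < 0.5 * base.volume.spacing[0]

    def test_spacing_mismatch_rejected(self, small_baseline):
        ceph = self._ceph(small_baseline)
        other = CephImage(ceph.data, ceph.spacing * 2, ceph.origin, "left")
        with pytest.raises(ValueError, match="spacing"):
            superimpose_2d(ceph, other, self._ref(small_baseline))


def _tooth_lms(shift=(0.0, 0.0, 0.0)):
    base = {
        "RU6.mb_cusp": np.array([30.0, 15.0, 10.0]),
        "LU6.mb_cusp": np.array([10.0, 15.0, 10.0]),
        "RU1.incisal_mid": np.array([21.0, 30.0, 12.0]),
        "LU1.incisal_mid": np.array([19.0, 30.0, 12.0]),
    }
    return (LandmarkSet(base),
            LandmarkSet({k: v + np.asarray(shift) for k, v in base.items()}))


class TestMeasurement:
    def test_no_motion_identity_transform_gives_zero(self):
        t1, t2 = _tooth_lms()
        recs = measure_tooth_displacement(t1, t2, RigidTransform.identity())
        assert all(r.x == 0.0 and r.y == 0.0 for r in recs)

    def test_anterior_shift_is_positive_x_for_every_tooth(self):
        """Axis convention: +2 mm anterior motion reads as x = +2.0, y = 0."""
        t1, t2 = _tooth_lms(shift=(0.0, 2.0, 0.0))
        for r in measure_tooth_displacement(t1, t2, RigidTransform.identity()):
            assert r.x == pytest.approx(2.0, abs=1e-9)
            assert r.y == pytest.approx(0.0, abs=1e-9)
        # and identically through the 2D path
        for r in measure_tooth_displacement(t1, t2, Rigid2D()):
            assert r.x == pytest.approx(2.0, abs=1e-9)

    def test_superior_shift_is_positive_y(self):
        t1, t2 = _tooth_lms(shift=(0.0, 0.0, 1.5))
        for r in measure_tooth_displacement(t1, t2, RigidTransform.identity()):
            assert r.y == pytest.approx(1.5, abs=1e-9)

    def test_missing_landmark_rejected(self):
        t1, t2 = _tooth_lms()
        del t1.entries["RU6.mb_cusp"]
        with pytest.raises(ValueError, match="missing tooth"):
            measure_tooth_displacement(t1, t2, RigidTransform.identity())


def _records(rng, n=15, noise=0.0, method=""):
    recs = []
    for i in range(n):
        for tooth in ("RU6", "LU6", "RU1", "LU1"):
            x, y = rng.normal(0, 2.0, 2)
            recs.append(ToothDisplacement(tooth, x + rng.normal(0, noise),
                                          y + rng.normal(0, noise),
                                          method=method, subject_id=f"s{i:02d}"))
    return recs


class TestAgreement:
    def test_identical_records_give_icc_one(self, rng):
        recs = _records(rng)
        table = method_agreement(recs, recs)
        assert (table["icc"] == 1.0).all()
        assert (table["band"] == "excellent").all()

    def test_noise_calibrated_icc_matches_variance_components(self):
        """Independent noise SD 1 on signals of SD 2 gives ICC -> 4/5 = 0.8."""
        rng = np.random.default_rng(11)
        n = 4000
        signal = rng.normal(0, 2.0, n)
        a = signal + rng.normal(0, 0.5, n) * 0 + rng.normal(0, 1.0, n)
        b = signal + rng.normal(0, 1.0, n)
        from maxstab.screw_validation import icc_absolute
        res = icc_absolute(np.column_stack([a, b]))
        assert res.estimate == pytest.approx(0.8, abs=0.02)

    def test_unmatched_records_rejected(self, rng):
        a = _records(rng, n=8)
        b = _records(rng, n=7)
        with pytest.raises(ValueError, match="unmatched"):
            method_agreement(a, b)

    def test_too_few_subjects_rejected(self, rng):
        a = _records(rng, n=3)
        with pytest.raises(ValueError, match=">= 5"):
            method_agreement(a, a)

    def test_band_boundaries(self, rng):
        from maxstab.evaluation import AGREEMENT_BANDS
        lookup = {icc: next(name for lo, name in AGREEMENT_BANDS if icc >= lo)
                  for icc in (0.95, 0.8, 0.6, 0.2)}
        assert lookup == {0.95: "excellent", 0.8: "good", 0.6: "moderate", 0.2: "poor"}


class TestSampleSize:
    def test_monotone_in_reliability_gap(self):
        ns = [icc_sample_size(0.8, r1) for r1 in (0.85, 0.9, 0.95, 0.99)]
        assert ns == sorted(ns, reverse=True)

    def test_published_configuration_magnitude(self):
        """(rho0=0.8, rho1=0.95, alpha=0.05, power=0.8, 2 raters) lands in the
        low teens; formula-dependent, so only the magnitude is checked."""
        n = icc_sample_size(0.8, 0.95, 0.05, 0.80, 2)
        assert 8 <= n <= 30

    def test_power_to_zero_shrinks_n(self):
        assert icc_sample_size(0.8, 0.95, power=0.05) <= icc_sample_size(0.8, 0.95, power=0.8)

    def test_invalid_rho_ordering(self):
        with pytest.raises(ValueError):
            icc_sample_size(0.95, 0.8)
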