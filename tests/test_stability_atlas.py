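import numpy as np
import pytest

from maxstab.core_io import BinaryMask, ImageVolume
from maxstab.fields import VectorField
from maxstab.stability_atlas import (StabilityThresholds, extract_nrs, grade,
                                     pool_magnitudes, surface_change,
                                     thresholds_from_field)


def _field_with_exact_stats(shape, mask, mean, sd, rng):
    """Masked values affinely rescaled to the requested sample mean/SD."""
    data = np.zeros(shape)
    vals = rng.random(int(mask.sum()))
    z = (vals - vals.mean()) / vals.std(ddof=1)
    data[mask] = mean + sd * z
    return ImageVolume(data, spacing=(0.5, 0.5, 0.5))


@pytest.fixture
def ball_mask():
    n = 24
    idx = np.indices((n, n, n))
    r = np.sqrt(((idx - n / 2 + 0.5) ** 2).sum(axis=0))
    return BinaryMask(r < 9, spacing=(0.5, 0.5, 0.5))


class TestThresholds:
    def test_published_statistics_give_published_cuts(self, ball_mask, rng):
        """A masked field with mean 1.80 mm / SD 0.60 mm grades at exactly
        1.2 / 1.8 / 2.4 mm."""
        pooled = _field_with_exact_stats(ball_mask.shape, ball_mask.data, 1.80, 0.60, rng)
        thr = thresholds_from_field(pooled, ball_mask)
        assert thr.cut1 == pytest.approx(1.2, abs=1e-12)
        assert thr.cut2 == pytest.approx(1.8, abs=1e-12)
        assert thr.cut3 == pytest.approx(2.4, abs=1e-12)

    def test_constant_field_degenerate(self, ball_mask):
        pooled = ImageVolume(np.full(ball_mask.shape, 2.0), spacing=(0.5, 0.5, 0.5))
        thr = thresholds_from_field(pooled, ball_mask)
        assert thr.degenerate

    def test_too_few_masked_voxels(self, ball_mask):
        tiny = BinaryMask(np.zeros(ball_mask.shape, bool), spacing=(0.5, 0.5, 0.5))
        tiny.data[0, 0, 0] = True
        with pytest.raises(ValueError, match=">= 2"):
            thresholds_from_field(ImageVolume(np.ones(ball_mask.shape),
                                              spacing=(0.5, 0.5, 0.5)), tiny)


class TestPooling:
    def test_identical_fields_pool_to_themselves(self, ball_mask, rng):
        f = _field_with_exact_stats(ball_mask.shape, ball_mask.data, 1.8, 0.6, rng)
        pooled = pool_magnitudes([f, f, f], ball_mask)
        np.testing.assert_allclose(pooled.data[ball_mask.data], f.data[ball_mask.data])

    def test_two_subject_voxel_average(self, ball_mask):
        a = ImageVolume(np.full(ball_mask.shape, 1.0), spacing=(0.5, 0.5, 0.5))
        b = ImageVolume(np.full(ball_mask.shape, 3.0), spacing=(0.5, 0.5, 0.5))
        pooled = pool_magnitudes([a, b], ball_mask)
        assert np.all(pooled.data[ball_mask.data] == 2.0)

    def test_matches_direct_mean_oracle(self, ball_mask, rng):
        fields = [_field_with_exact_stats(ball_mask.shape, ball_mask.data, 2.0, 0.5, rng)
                  for _ in range(4)]
        pooled = pool_magnitudes(fields, ball_mask)
        oracle = np.mean([f.data for f in fields], axis=0)
        np.testing.assert_allclose(pooled.data[ball_mask.data], oracle[ball_mask.data])

    def test_grid_mismatch_rejected(self, ball_mask):
        a = ImageVolume(np.zeros(ball_mask.shape), spacing=(0.5, 0.5, 0.5))
        b = ImageVolume(np.zeros((4, 4, 4)), spacing=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="template grid"):
            pool_magnitudes([a, b], ball_mask)


class TestGrading:
    thr = StabilityThresholds(1.8, 0.6)

    def _grade_single(self, value, ball_mask):
        pooled = ImageVolume(np.full(ball_mask.shape, value), spacing=(0.5, 0.5, 0.5))
        labels = grade(pooled, self.thr, ball_mask)
        return np.unique(labels.data[ball_mask.data])

    @pytest.mark.parametrize("value,level", [
        (1.0, 1), (1.2, 1),     # boundary inclusive: "less than or equal to"
        (1.5, 2), (1.8, 2), (2.1, 3), (2.4, 3), (99.0, 4)])
    def test_level_assignment(self, value, level, ball_mask):
        assert self._grade_single(value, ball_mask).tolist() == [level]

    def test_partition_exhaustive_and_exclusive(self, ball_mask, rng):
        pooled = _field_with_exact_stats(ball_mask.shape, ball_mask.data, 1.8, 0.6, rng)
        labels = grade(pooled, self.thr, ball_mask)
        inside = labels.data[ball_mask.data]
        assert set(np.unique(inside)) <= {1, 2, 3, 4}
        assert np.all(inside > 0)
        assert np.all(labels.data[~ball_mask.data] == 0)

    def test_regrading_idempotent(self, ball_mask, rng):
        pooled = _field_with_exact_stats(ball_mask.shape, ball_mask.data, 1.8, 0.6, rng)
        l1 = grade(pooled, self.thr, ball_mask)
        l2 = grade(pooled, self.thr, ball_mask)
        np.testing.assert_array_equal(l1.data, l2.data)


class TestNRS:
    def test_all_level_one_returns_whole_mask(self, ball_mask):
        pooled = ImageVolume(np.full(ball_mask.shape, 0.5), spacing=(0.5, 0.5, 0.5))
        labels = grade(pooled, StabilityThresholds(1.8, 0.6), ball_mask)
        nrs = extract_nrs(labels, closing_radius=0)
        np.testing.assert_array_equal(nrs.data, ball_mask.data)

    def test_isolated_voxel_removed_then_error(self, ball_mask):
        labels = np.zeros(ball_mask.shape, np.uint8)
        labels[2, 2, 2] = 1
        vol = ImageVolume(labels, spacing=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="no stable region"):
            extract_nrs(vol, min_component=100)

    def test_no_level_one_error(self, ball_mask):
        labels = ImageVolume(np.full(ball_mask.shape, 4, np.uint8), spacing=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="no stable region"):
            extract_nrs(labels)


class TestSurfaceChange:
    def _radial_field(self, ball_mask, magnitude=2.0, inward=False):
        n = ball_mask.shape[0]
        idx = np.indices(ball_mask.shape).astype(np.float64)
        c = (np.asarray(ball_mask.shape) - 1) / 2
        vec = np.moveaxis(idx, 0, -1) - c
        norm = np.maximum(np.linalg.norm(vec, axis=-1, keepdims=True), 1e-9)
        data = magnitude * vec / norm * (-1 if inward else 1)
        return VectorField(data.astype(np.float32), spacing=(0.5, 0.5, 0.5))

    def test_outward_field_reads_as_deposition(self, ball_mask):
        sm = surface_change(self._radial_field(ball_mask), ball_mask)
        vals = sm.signed_mm.data[sm.surface.data]
        assert (vals > 0).mean() > 0.99
        assert vals.mean() == pytest.approx(2.0, rel=0.15)

    def test_inward_field_reads_as_resorption(self, ball_mask):
        sm = surface_change(self._radial_field(ball_mask, inward=True), ball_mask)
        assert (sm.signed_mm.data[sm.surface.data] < 0).mean() > 0.99

    def test_sign_flips_with_normals(self, ball_mask):
        a = surface_change(self._radial_field(ball_mask), ball_mask)
        b = surface_change(self._radial_field(ball_mask), ball_mask, flip_normals=True)
        np.testing.assert_allclose(b.signed_mm.data, -a.signed_mm.data, atol=1e-9)

    def test_zero_field_all_zero(self, ball_mask):
        fld = VectorField(np.zeros(ball_mask.shape + (3,), np.float32), spacing=(0.5, 0.5, 0.5))
        sm = surface_change(fld, ball_mask)
        assert np.abs(sm.signed_mm.data).max() == 0.0

    def test_mask_without_interior_rejected(self):
        shell = np.zeros((8, 8, 8), bool)
        shell[3, 3, 3] = True
        with pytest.raises(ValueError, match="interior"):
            surface_change(VectorField(np.zeros((8, 8, 8, 3), np.float32)),
                           BinaryMask(shell, spacing=(1, 1, 1)))

    def test_phantom_pole_elongation_recovered(self, small_pair, small_spec):
        """Signed normal displacement near the planted tuberosity pole
        approximates the planted elongation."""
        baseline, _, gt = small_pair
        sm = surface_change(gt.true_field, baseline.mask)
        pole = baseline.geometry.pole_center
        pts = sm.surface.voxel_to_physical(np.argwhere(sm.surface.data))
        near = np.linalg.norm(pts - pole, axis=1) < 2.0
        vals = sm.signed_mm.data[sm.surface.data][near]
        assert vals.mean() == pytest.approx(small_spec.pole_magnitude, rel=0.2)
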