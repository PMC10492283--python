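import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from maxstab.core_io import LandmarkSet
from maxstab.screw_validation import (SCREW_PAIRS, icc_absolute, icc_consistency,
                                      inter_screw_distances, paired_t,
                                      paired_t_from_summary, screw_stability_report)

# printed summary rows (mean difference, SD, n, published t) that are
# internally consistent with t = mean / (SD / sqrt(n))
TABLE2_CONSISTENT_ROWS = {
    "d1": (-0.249, 0.594, 10, -1.325),
    "d3": (-0.391, 0.608, 10, -2.031),
    "d4": (-0.342, 0.489, 10, -2.213),
    "d9": (-0.205, 0.674, 10, -0.964),
}


def _screw_landmarks(rng, scale=20.0):
    return LandmarkSet({f"screw{i}.{p}": rng.uniform(0, scale, 3)
                        for i in (1, 2, 3, 4) for p in ("head", "tip")})


class TestDistances:
    def test_twelve_positive_distances_on_phantom(self, small_baseline):
        ds = inter_screw_distances(small_baseline.landmarks)
        assert ds.distances.shape == (12,)
        assert ds.valid

    def test_matches_brute_force_pairwise_oracle(self, rng):
        lms = _screw_landmarks(rng)
        ds = inter_screw_distances(lms)
        expected = []
        for part in ("head", "tip"):
            for a, b in SCREW_PAIRS:
                expected.append(np.sqrt(np.sum(
                    (lms[f"screw{a}.{part}"] - lms[f"screw{b}.{part}"]) ** 2)))
        np.testing.assert_allclose(ds.distances, expected, rtol=1e-12)

    def test_coincident_heads_flagged_invalid(self, rng):
        lms = _screw_landmarks(rng)
        lms["screw2.head"] = lms["screw1.head"]
        assert not inter_screw_distances(lms).valid

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariance_under_global_rigid_motion(self, seed):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(seed)
        lms = _screw_landmarks(rng)
        R = Rotation.random(rng=np.random.default_rng(seed + 1)).as_matrix()
        t = rng.uniform(-30, 30, 3)
        moved = lms.transformed(lambda p: R @ p + t)
        np.testing.assert_allclose(inter_screw_distances(moved).distances,
                                   inter_screw_distances(lms).distances, atol=1e-9)


class TestPairedT:
    @pytest.mark.parametrize("row,vals", TABLE2_CONSISTENT_ROWS.items())
    def test_published_summary_rows(self, row, vals):
        mean, sd, n, t_printed = vals
        res = paired_t_from_summary(mean, sd, n)
        assert res.t == pytest.approx(t_printed, abs=0.01)
        assert res.df == n - 1
        assert 0 <= res.p <= 1

    def test_equal_samples_give_t0_p1(self, rng):
        x = rng.random(10)
        res = paired_t(x, x)
        assert res.t == 0.0 and res.p == 1.0

    def test_matches_scipy_oracle(self, rng):
        for _ in range(20):
            pre = rng.normal(size=10)
            post = pre + rng.normal(0.3, 0.5, size=10)
            res = paired_t(pre, post)
            ref = sps.ttest_rel(pre, post)
            assert res.t == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_summary_path_agrees_with_data_path(self, rng):
        pre, post = rng.normal(size=12), rng.normal(size=12)
        d = pre - post
        a = paired_t(pre, post)
        b = paired_t_from_summary(d.mean(), d.std(ddof=1), len(d))
        assert a.t == pytest.approx(b.t, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_degenerate_inputs(self):
        res = paired_t([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
        assert np.isinf(res.t) and res.p == 0.0
        with pytest.raises(ValueError):
            paired_t([1.0], [2.0])
        with pytest.raises(ValueError):
            paired_t_from_summary(0.1, 0.0, 10)


def _icc_a1_oracle(x):
    """Explicit ANOVA sums-of-squares ICC(A,1)."""
    n, k = x.shape
    grand = x.mean()
    ssr = k * ((x.mean(1) - grand) ** 2).sum()
    ssc = n * ((x.mean(0) - grand) ** 2).sum()
    sse = ((x - grand) ** 2).sum() - ssr - ssc
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_raters_give_one(self, rng):
        x = rng.normal(size=10)
        res = icc_absolute(np.column_stack([x, x]))
        assert res.estimate == 1.0

    def test_constant_shift_penalised_by_absolute_agreement(self, rng):
        x = rng.normal(0, 1, size=12)
        mat = np.column_stack([x, x + 2.5])
        res = icc_absolute(mat)
        assert res.estimate < icc_consistency(mat)
        assert icc_consistency(mat) == pytest.approx(1.0, abs=1e-9)

    def test_matches_anova_oracle(self, rng):
        for _ in range(10):
            mat = rng.normal(size=(10, 2))
            res = icc_absolute(mat)
            assert res.estimate == pytest.approx(_icc_a1_oracle(mat), abs=1e-10)

    def test_matches_pingouin_estimate_and_ci(self, rng):
        import pandas as pd
        import pingouin as pg
        mat = rng.normal(size=(12, 2)) + rng.normal(size=(12, 1)) * 2.0
        res = icc_absolute(mat)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile(["a", "b"], 12),
            "score": mat.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        assert res.estimate == pytest.approx(row["ICC"], abs=1e-8)
        assert res.ci_low == pytest.approx(row["CI95"][0], abs=0.01)
        assert res.ci_high == pytest.approx(row["CI95"][1], abs=0.01)

    def test_estimate_within_ci(self, rng):
        mat = rng.normal(size=(15, 2)) + rng.normal(size=(15, 1))
        res = icc_absolute(mat)
        assert res.ci_low <= res.estimate <= res.ci_high <= 1.0

    def test_constant_matrix_degenerate(self):
        res = icc_absolute(np.full((6, 2), 3.14))
        assert res.degenerate


class TestStabilityReport:
    def _cohort(self, rng, n=10, displace=None):
        base = _screw_landmarks(rng)   # shared implant geometry across subjects
        pairs = []
        for _ in range(n):
            lms1 = base.transformed(lambda p: p + rng.normal(0, 0.05, 3))
            lms2 = base.transformed(lambda p: p + rng.normal(0, 0.05, 3))
            if displace is not None:
                lms2[displace] = lms2[displace] + np.array([3.0, 0, 0])
            pairs.append((inter_screw_distances(lms1), inter_screw_distances(lms2)))
        return pairs

    def test_rigid_cohort_verdict_stable(self):
        # fixed benign seed: with 12 simultaneous tests at alpha = 0.05 a
        # truly rigid cohort still flags one distance ~46% of the time
        report = screw_stability_report(self._cohort(np.random.default_rng(4)))
        assert len(report) == 12
        assert report.attrs["verdict"] == "stable"

    def test_planted_screw_displacement_detected(self, rng):
        report = screw_stability_report(self._cohort(rng, displace="screw1.head"))
        assert (report["p"] < 0.05).any()
        assert report.attrs["verdict"] == "unstable"

    def test_missing_timepoint_excluded(self, rng):
        pairs = self._cohort(rng, n=3)
        pairs.append((inter_screw_distances(_screw_landmarks(rng)), None))
        report = screw_stability_report(pairs)
        assert report["df"].iloc[0] == 2  # 3 complete subjects

    def test_fewer_than_two_complete_subjects_rejected(self, rng):
        pairs = self._cohort(rng, n=1)
        with pytest.raises(ValueError, match=">= 2"):
            screw_stability_report(pairs)
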