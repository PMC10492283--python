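"""Mini-screw stability statistics.

Before mini-screws can serve as fiducials, their mutual geometry must be
shown constant across the observation interval: the 6 head-to-head and 6
tip-to-tip Euclidean distances over the 4 screws are compared between
timepoints with paired t tests, and examiner agreement is quantified with
the two-way random-effects absolute-agreement single-measure intraclass
correlation, ICC(A,1).

The distance labels d1..d12 follow lexicographic screw-pair order —
(1,2), (1,3), (1,4), (2,3), (2,4), (3,4) — heads first (d1-d6), then tips
(d7-d12) in the same order.  The labels are reported in output headers;
any fixed order reproduces the statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import LandmarkSet

logger = logging.getLogger("maxstab")

__all__ = [
    "DistanceSet", "PairedTResult", "ICCResult",
    "inter_screw_distances", "paired_t", "paired_t_from_summary",
    "icc_absolute", "icc_consistency", "screw_stability_report",
    "SCREW_PAIRS",
]

SCREW_PAIRS: tuple[tuple[int, int], ...] = tuple(combinations((1, 2, 3, 4), 2))


@dataclass
class DistanceSet:
    """The 12 inter-screw distances (mm) of one scan."""

    distances: np.ndarray          # shape (12,), d1..d12
    subject_id: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float).reshape(12)

    @property
    def valid(self) -> bool:
        return bool(np.all(self.distances > 0))

    def labels(self) -> list[str]:
        return [f"d{i}" for i in range(1, 13)]


@dataclass
class PairedTResult:
    mean_diff: float
    sd_diff: float
    n: int
    t: float
    p: float

    @property
    def df(self) -> int:
        return self.n - 1


@dataclass
class ICCResult:
    """ICC point estimate with 95% CI (two-way random, single measure)."""

    estimate: float
    ci_low: float
    ci_high: float
    model: str = "two-way random, absolute agreement, single rater (A,1)"
    degenerate: bool = False


def inter_screw_distances(landmarks: LandmarkSet) -> DistanceSet:
    """Compute d1..d12 from the 4 screw head/tip landmark pairs."""
    for i in (1, 2, 3, 4):
        for part in ("head", "tip"):
            if f"screw{i}.{part}" not in landmarks:
                raise ValueError(f"missing screw landmark screw{i}.{part}")
    out = []
    for part in ("head", "tip"):
        for a, b in SCREW_PAIRS:
            out.append(float(np.linalg.norm(
                landmarks[f"screw{a}.{part}"] - landmarks[f"screw{b}.{part}"])))
    ds = DistanceSet(np.asarray(out))
    if not ds.valid:
        logger.warning("inter_screw_distances: zero-length distance flagged invalid")
    return ds


def paired_t(pre, post) -> PairedTResult:
    """Two-sided paired t test on matched measurements.

    ``t = mean(pre - post) / (sd / sqrt(n))`` with sample SD (n-1 denominator)
    and Student-t reference with n-1 degrees of freedom.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D vectors of equal length")
    n = pre.size
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    if not (np.all(np.isfinite(pre)) and np.all(np.isfinite(post))):
        raise ValueError("non-finite input")
    d = pre - post
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(mean, sd, n, 0.0, 1.0)
        return PairedTResult(mean, sd, n, math.copysign(math.inf, mean), 0.0)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return PairedTResult(mean, sd, n, t, float(p))


def paired_t_from_summary(mean_diff: float, sd_diff: float, n: int) -> PairedTResult:
    """Paired t from printed summary statistics (verification path)."""
    if sd_diff <= 0:
        raise ValueError("sd_diff must be positive")
    if n < 2:
        raise ValueError("need n >= 2")
    t = mean_diff / (sd_diff / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return PairedTResult(float(mean_diff), float(sd_diff), int(n), float(t), float(p))


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float, int, int]:
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((x - grand) ** 2))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_absolute(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is subjects x raters with no missing cells.  The point
    estimate is ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)`` and
    the CI uses the F-based construction with Satterthwaite degrees of
    freedom.  Constant ratings across all cells are degenerate (no
    between-subject variance to agree about).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 5 or x.shape[1] < 2:
        raise ValueError("ratings must be subjects x raters with >= 5 subjects, >= 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite cells")
    if float(x.std()) == 0.0:
        return ICCResult(float("nan"), float("nan"), float("nan"), degenerate=True)
    if bool((x == x[:, [0]]).all()):    # perfect agreement, exactly
        return ICCResult(1.0, 1.0, 1.0)
    msr, msc, mse, n, k = _anova_mean_squares(x)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else float("nan")
    # McGraw & Wong CI
    r = icc
    a = k * r / (n * (1.0 - r)) if r < 1 else float("inf")
    b = 1.0 + k * r * (n - 1) / (n * (1.0 - r)) if r < 1 else float("inf")
    if not np.isfinite(a):
        return ICCResult(1.0, 1.0, 1.0)
    nu = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
    f_l = sps.f.ppf(1 - alpha / 2, n - 1, nu)
    f_u = sps.f.ppf(1 - alpha / 2, nu, n - 1)
    lo = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return ICCResult(float(icc), float(lo), float(hi))


def icc_consistency(ratings: np.ndarray) -> float:
    """ICC(C,1) point estimate (consistency; shift-invariant counterpart)."""
    x = np.asarray(ratings, dtype=float)
    msr, _, mse, _, k = _anova_mean_squares(x)
    return float((msr - mse) / (msr + (k - 1) * mse))


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------

def screw_stability_report(cohort_distances, alpha: float = 0.05) -> pd.DataFrame:
    """Paired t per distance index over a cohort of (pre, post) DistanceSets.

    ``cohort_distances`` iterates over per-subject ``(pre, post)`` tuples;
    subjects with a missing timepoint are excluded with a warning.  Returns
    a 12-row table (distance_id, mean_diff_mm, sd_mm, t, df, p) whose
    ``attrs["verdict"]`` is "stable" iff no distance changed significantly.
    """
    pairs = []
    for item in cohort_distances:
        pre, post = item
        if pre is None or post is None:
            logger.warning("screw_stability_report: subject with missing timepoint excluded")
            continue
        pairs.append((pre.distances, post.distances))
    if len(pairs) < 2:
        raise ValueError("need >= 2 complete subjects")
    pre_m = np.array([p for p, _ in pairs])
    post_m = np.array([q for _, q in pairs])
    rows = []
    for j in range(12):
        res = paired_t(pre_m[:, j], post_m[:, j])
        rows.append((f"d{j + 1}", res.mean_diff, res.sd_diff, res.t, res.df, res.p))
    df = pd.DataFrame(rows, columns=["distance_id", "mean_diff_mm", "sd_mm", "t", "df", "p"])
    df.attrs["verdict"] = "stable" if bool((df["p"] >= alpha).all()) else "unstable"
    df.attrs["alpha"] = alpha
    return df
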