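"""Tooth-movement measurement and 3D-vs-2D method agreement.

The validation question: do tooth displacements measured after 3D
NRS-based superimposition agree with the classic 2D lateral-cephalogram
superimposition (Björk-style reference structures)?  Lateral cephalograms
are simulated by parallel projection of a half-volume along the
left-right axis; the manual Björk tracing step is replaced by a
deterministic masked 2D rigid registration whose reference is the
projected NRS.  Agreement per tooth-axis variable is ICC(A,1) with its
95% CI, banded excellent / good / moderate / poor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.ndimage import map_coordinates
from scipy.optimize import minimize

from .core_io import BinaryMask, ImageVolume, LandmarkSet
from .screw_validation import icc_absolute
from .registration import RigidTransform

logger = logging.getLogger("maxstab")

__all__ = [
    "ToothDisplacement", "CephImage", "Rigid2D", "ReferenceFrame",
    "project_lateral", "superimpose_2d", "measure_tooth_displacement",
    "method_agreement", "icc_sample_size", "TOOTH_LANDMARKS",
]

TOOTH_LANDMARKS = {
    "RU6": "RU6.mb_cusp", "LU6": "LU6.mb_cusp",
    "RU1": "RU1.incisal_mid", "LU1": "LU1.incisal_mid",
}


@dataclass
class ToothDisplacement:
    """Sagittal (x, positive anterior) and vertical (y, positive superior)
    displacement of one tooth landmark, mm."""

    tooth: str
    x: float
    y: float
    method: str = ""              # "NRS-3D" | "Bjork-2D"
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.tooth not in TOOTH_LANDMARKS:
            raise ValueError(f"unknown tooth id {self.tooth!r}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("non-finite displacement")


@dataclass
class CephImage:
    """Simulated lateral cephalogram: 2D array over (anterior, superior) axes."""

    data: np.ndarray              # (ny, nz)
    spacing: np.ndarray           # (2,) mm
    origin: np.ndarray            # (2,) mm, physical (y, z) of pixel (0, 0)
    side: str                     # "left" | "right"
    projection: str = "mip"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(2)
        self.origin = np.asarray(self.origin, dtype=float).reshape(2)
        if np.any(self.spacing <= 0):
            raise ValueError("non-positive pixel spacing")

    def physical_to_pixel(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - self.origin) / self.spacing


@dataclass
class Rigid2D:
    """2D rotation + translation on (anterior, superior) coordinates (mm)."""

    angle_deg: float = 0.0
    translation: np.ndarray = dc_field(default_factory=lambda: np.zeros(2))
    center: np.ndarray = dc_field(default_factory=lambda: np.zeros(2))

    def matrix(self) -> np.ndarray:
        a = math.radians(self.angle_deg)
        return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        R = self.matrix()
        return (pts - self.center) @ R.T + self.center + np.asarray(self.translation)

    def inverse(self) -> "Rigid2D":
        R = self.matrix().T
        t = np.asarray(self.translation)
        inv = Rigid2D(-self.angle_deg, center=self.center)
        inv.translation = -R @ t
        return inv


@dataclass
class ReferenceFrame:
    """Measurement axes in the T1 frame: sagittal positive anterior,
    vertical positive superior (grid axes 1 and 2 by construction)."""

    anterior: np.ndarray = dc_field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    superior: np.ndarray = dc_field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def project(self, vec3: np.ndarray) -> tuple[float, float]:
        v = np.asarray(vec3, dtype=float)
        return float(v @ self.anterior), float(v @ self.superior)


# ---------------------------------------------------------------------------
# lateral projection
# ---------------------------------------------------------------------------

def project_lateral(vol: ImageVolume, side: str, mode: str = "mip",
                    midsagittal_index: int | None = None) -> CephImage:
    """Parallel projection of one half of the volume along the left-right axis.

    ``side="right"`` keeps voxels with index above the midsagittal plane
    (right = positive axis 0), ``"left"`` the rest.  Default projection is
    maximum intensity; ``mode="mean"`` averages.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    nx = vol.shape[0]
    mid = nx // 2 if midsagittal_index is None else int(midsagittal_index)
    if not (0 < mid < nx):
        raise ValueError("midsagittal plane outside the volume")
    half = vol.data[mid:] if side == "right" else vol.data[:mid]
    if isinstance(vol, BinaryMask) or vol.data.dtype == bool:
        proj = half.any(axis=0)
    elif mode == "mean":
        proj = half.mean(axis=0)
    else:
        proj = half.max(axis=0)
    return CephImage(np.asarray(proj), vol.spacing[1:], vol.origin[1:], side, mode)


# ---------------------------------------------------------------------------
# 2D masked rigid superimposition
# ---------------------------------------------------------------------------

def superimpose_2d(ceph1: CephImage, ceph2: CephImage, reference_mask: np.ndarray,
                   xtol: float = 1e-4, n_restarts: int = 4,
                   smooth_px: float = 1.0) -> Rigid2D:
    """2D rigid transform mapping ``ceph2`` coordinates into the ``ceph1`` frame.

    The similarity (normalised cross-correlation) is evaluated only on the
    reference-mask pixels — in the pipeline, the lateral projection of the
    NRS, standing in for manually traced stable structures.  Both images
    are pre-smoothed (``smooth_px``) so pixel noise in the small reference
    patch cannot create spurious optima, and a coarse exhaustive sweep over
    the plausible repositioning range precedes Powell refinement of the
    ``1 + n_restarts`` best cells.  Fully deterministic.
    """
    if not np.allclose(ceph1.spacing, ceph2.spacing):
        raise ValueError("cephalogram pixel spacings differ")
    mask = np.asarray(reference_mask, dtype=bool)
    if mask.shape != ceph1.data.shape or not mask.any():
        raise ValueError("reference mask empty or mismatched")
    from scipy.ndimage import gaussian_filter
    f1 = np.asarray(ceph1.data, dtype=np.float32)
    m2 = np.asarray(ceph2.data, dtype=np.float32)
    if smooth_px > 0:
        f1 = gaussian_filter(f1, smooth_px)
        m2 = gaussian_filter(m2, smooth_px)
    pix = np.argwhere(mask).astype(float)
    pts = pix * ceph1.spacing + ceph1.origin
    fvals = f1.astype(np.float64)[mask]
    center = pts.mean(axis=0)
    cval = float(np.percentile(m2, 1))

    def objective(theta):
        T_inv = Rigid2D(theta[0], np.asarray(theta[1:]), center=center)
        q = T_inv.apply(pts)
        coords = ((q - ceph2.origin) / ceph2.spacing).T
        mvals = map_coordinates(m2, coords, order=1, mode="constant",
                                cval=cval).astype(np.float64)
        fz, mz = fvals - fvals.mean(), mvals - mvals.mean()
        denom = math.sqrt(float(fz @ fz) * float(mz @ mz))
        return 1.0 if denom < 1e-12 else 1.0 - float(fz @ mz) / denom

    # exhaustive coarse sweep over the plausible repositioning range (the
    # masked objective is cheap and multimodal), then local refinement of
    # the best cells
    angles = np.arange(-8.0, 8.01, 1.0)
    shifts = np.arange(-6.0, 6.01, 0.75)
    grid = [(a, ty, tz) for a in angles for ty in shifts for tz in shifts]
    scores = np.array([objective(np.array(g)) for g in grid])
    order = np.argsort(scores)[: 1 + n_restarts]
    best = None
    for k in order:
        res = minimize(objective, np.array(grid[k]), method="Powell",
                       options={"xtol": xtol, "ftol": 1e-9, "maxiter": 80})
        if best is None or res.fun < best.fun:
            best = res
    if best.fun > 0.9:
        raise RuntimeError("2D superimposition failed to converge")
    return Rigid2D(best.x[0], np.asarray(best.x[1:]), center=center).inverse()


# ---------------------------------------------------------------------------
# tooth displacement
# ---------------------------------------------------------------------------

def measure_tooth_displacement(landmarks_t1: LandmarkSet, landmarks_t2: LandmarkSet,
                               transform: "RigidTransform | Rigid2D",
                               frame: ReferenceFrame | None = None,
                               method: str = "", subject_id: str = "",
                               ) -> list[ToothDisplacement]:
    """Per-tooth (sagittal, vertical) displacement in the T1 frame.

    ``transform`` maps T2 coordinates into the T1 frame: a 3D
    :class:`RigidTransform` for NRS superimposition, or a :class:`Rigid2D`
    acting on projected (anterior, superior) coordinates for the
    cephalometric path.  Displacement = transformed T2 landmark minus T1
    landmark, projected on the frame axes.
    """
    frame = frame or ReferenceFrame()
    out = []
    for tooth, lm_name in TOOTH_LANDMARKS.items():
        if lm_name not in landmarks_t1 or lm_name not in landmarks_t2:
            raise ValueError(f"missing tooth landmark {lm_name}")
        p1, p2 = landmarks_t1[lm_name], landmarks_t2[lm_name]
        if isinstance(transform, Rigid2D):
            q1 = np.array(frame.project(p1))
            q2 = transform.apply(np.array(frame.project(p2)))
            dx, dy = float(q2[0] - q1[0]), float(q2[1] - q1[1])
        else:
            d = transform.apply(p2[None])[0] - p1
            dx, dy = frame.project(d)
        out.append(ToothDisplacement(tooth, dx, dy, method=method, subject_id=subject_id))
    return out


AGREEMENT_BANDS = ((0.9, "excellent"), (0.75, "good"), (0.5, "moderate"), (-np.inf, "poor"))


def method_agreement(records_3d, records_2d) -> pd.DataFrame:
    """Per tooth-axis variable: mean (SD) per method and ICC(A,1) with CI.

    Records must cover the same subjects and teeth under both methods
    (matched on subject id); at least 5 subjects.  The qualitative band is
    excellent >= 0.9, good >= 0.75, moderate >= 0.5, else poor.
    """
    def table(records):
        rows = [(r.subject_id, r.tooth, r.x, r.y) for r in records]
        df = pd.DataFrame(rows, columns=["subject", "tooth", "x", "y"])
        return df.set_index(["subject", "tooth"]).sort_index()

    t3, t2 = table(records_3d), table(records_2d)
    if not t3.index.equals(t2.index):
        raise ValueError("unmatched records between methods")
    n_subj = t3.index.get_level_values("subject").nunique()
    if n_subj < 5:
        raise ValueError("need >= 5 matched subjects")
    rows = []
    for tooth in TOOTH_LANDMARKS:
        for axis in ("x", "y"):
            a = t3.xs(tooth, level="tooth")[axis].to_numpy()
            b = t2.xs(tooth, level="tooth")[axis].to_numpy()
            icc = icc_absolute(np.column_stack([a, b]))
            band = next(name for lo, name in AGREEMENT_BANDS if icc.estimate >= lo)
            rows.append((f"{tooth}-{axis}", a.mean(), a.std(ddof=1), b.mean(),
                         b.std(ddof=1), icc.estimate, icc.ci_low, icc.ci_high, band))
    return pd.DataFrame(rows, columns=["variable", "mean3d", "sd3d", "mean2d", "sd2d",
                                       "icc", "ci_low", "ci_high", "band"])


def icc_sample_size(rho0: float, rho1: float, alpha: float = 0.05,
                    power: float = 0.80, raters: int = 2) -> int:
    """Subjects needed to distinguish reliability rho1 from the null rho0.

    Walter-Eliasziw-Donner approximation (one-sided, k raters): with
    theta_i = rho_i / (1 - rho_i) and C0 = (1 + k theta0) / (1 + k theta1),

        n = 1 + 2 k (z_{1-alpha} + z_{1-beta})^2 / ((k - 1) ln(C0)^2),

    rounded up.  Reported as a utility; published reliability formulas
    differ in sidedness and rounding by a few subjects.
    """
    if not (0 < rho0 < rho1 < 1):
        raise ValueError("require 0 < rho0 < rho1 < 1")
    if raters < 2:
        raise ValueError("need >= 2 raters")
    k = raters
    za = sps.norm.ppf(1 - alpha)
    zb = sps.norm.ppf(power)
    theta0, theta1 = rho0 / (1 - rho0), rho1 / (1 - rho1)
    c0 = (1 + k * theta0) / (1 + k * theta1)
    n = 1 + 2 * k * (za + zb) ** 2 / ((k - 1) * math.log(c0) ** 2)
    return max(2, math.ceil(n))
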