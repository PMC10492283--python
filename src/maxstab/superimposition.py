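"""NRS-based regional superimposition.

A new T1/T2 pair is superimposed by (1) carrying the template-space NRS
mask into the subject's T1 frame through the template-subject
correspondence and (2) estimating the rigid transform that best aligns the
two images over NRS voxels only.  Because the NRS is, by definition, the
region that does not remodel, the masked rigid fit recovers the pure
positional change between scans without being dragged by growth elsewhere
— the core advantage over whole-volume rigid registration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import minimize
from .morphology import remove_small_components

from .core_io import BinaryMask, ImageVolume
from .fields import VectorField, warp_scalar
from .registration import RigidTransform

logger = logging.getLogger("maxstab")

__all__ = ["MaskedRigidConfig", "SuperimpositionResult",
           "reverse_map_nrs", "masked_rigid_register"]


def reverse_map_nrs(nrs_mask: BinaryMask, subject_to_template: VectorField,
                    min_component: int = 100) -> BinaryMask:
    """Carry the template-space NRS mask into a subject's frame.

    ``subject_to_template`` is the pullback field on the subject grid whose
    value at a subject voxel points to its template correspondent (the
    backward field of a template-to-subject registration); the mask is
    warped with nearest-neighbour interpolation and cleaned of small
    components.
    """
    warped = warp_scalar(nrs_mask, subject_to_template, order=0)
    data = remove_small_components(warped.data, min_component)
    if not data.any():
        raise ValueError("reverse-mapped NRS is empty")
    return BinaryMask(data, warped.spacing, warped.origin, warped.direction)


@dataclass
class MaskedRigidConfig:
    metric: str = "ncc"          # "ncc" | "mse", evaluated at mask voxels only
    max_points: int = 20000      # deterministic stride subsample of mask voxels
    coarse_points: int = 4000    # subsample for the multi-start search stage
    n_restarts: int = 6          # extra starts beside identity (coarse stage)
    perturb_deg: float = 4.0     # restart perturbation scale (1 deg ~ 1 mm)
    perturb_mm: float = 4.0
    seed: int = 0
    xtol: float = 1e-3           # Powell tolerance in scaled parameters
    max_restarts_without_convergence: int = 3


@dataclass
class SuperimpositionResult:
    transform: RigidTransform    # maps moving (T2) points into the fixed (T1) frame
    similarity: float            # final metric value (lower is better)
    nrs_subject: BinaryMask
    iterations: int


def _metric(fvals: np.ndarray, mvals: np.ndarray, kind: str) -> float:
    if kind == "mse":
        return float(np.mean((fvals - mvals) ** 2)) / max(float(fvals.var()), 1e-12)
    fz = fvals - fvals.mean()
    mz = mvals - mvals.mean()
    denom = np.sqrt(float(fz @ fz) * float(mz @ mz))
    if denom < 1e-12:
        return 1.0
    return 1.0 - float(fz @ mz) / denom


def masked_rigid_register(fixed: ImageVolume, moving: ImageVolume, mask: BinaryMask,
                          config: MaskedRigidConfig | None = None) -> SuperimpositionResult:
    """Rigid transform (moving -> fixed frame) optimal over mask voxels only.

    Six parameters (Euler angles about the mask centroid, translations;
    scaled 1 degree ~ 1 mm) are optimised derivative-free (Powell) from
    identity plus seeded restarts; the similarity samples the moving image
    at the back-projected mask voxel positions only, so irregularly shaped
    reference regions cost nothing extra.  Deterministic given config.
    """
    cfg = config or MaskedRigidConfig()
    if not fixed.same_grid(mask):
        raise ValueError("mask must live on the fixed grid")
    if mask.n_voxels < 50:
        raise ValueError(f"mask too small ({mask.n_voxels} voxels)")
    idx_all = np.argwhere(mask.data)
    mdata = np.asarray(moving.data, dtype=np.float32)
    cval = float(np.percentile(mdata, 1))
    inv_aff = np.linalg.inv(moving.affine)
    fdata = np.asarray(fixed.data, dtype=np.float64)
    n_eval = 0

    center = fixed.voxel_to_physical(idx_all[::7]).mean(axis=0)

    def make_objective(idx):
        pts = fixed.voxel_to_physical(idx).astype(np.float64)
        fvals = fdata[tuple(idx.T)]

        def objective(theta: np.ndarray) -> float:
            nonlocal n_eval
            n_eval += 1
            # theta parametrises the inverse map (fixed frame -> moving frame)
            T_inv = RigidTransform.from_params(theta[:3], theta[3:], center=center)
            q = T_inv.apply(pts)
            vox = q @ inv_aff[:3, :3].T + inv_aff[:3, 3]
            mvals = map_coordinates(mdata, vox.T, order=1, mode="constant", cval=cval)
            # soft trust region: serial scans of one patient are coarsely
            # pre-positioned, distant optima are spurious
            excess = np.maximum(np.abs(theta) - np.array([15.0] * 3 + [10.0] * 3), 0.0)
            return (_metric(fvals, mvals.astype(np.float64), cfg.metric)
                    + 0.05 * float(excess @ excess))
        return objective

    # stage 1: multi-start on a coarse subsample to find the right basin
    coarse_obj = make_objective(
        idx_all[::max(1, int(np.ceil(len(idx_all) / cfg.coarse_points)))])
    rng = np.random.default_rng(cfg.seed)
    starts = [np.zeros(6)]
    for _ in range(cfg.n_restarts):
        starts.append(np.concatenate([
            rng.uniform(-cfg.perturb_deg, cfg.perturb_deg, 3),
            rng.uniform(-cfg.perturb_mm, cfg.perturb_mm, 3)]))
    coarse_best = None
    n_fail = 0
    for x0 in starts:
        res = minimize(coarse_obj, x0, method="Powell",
                       options={"xtol": 10 * cfg.xtol, "ftol": 1e-6, "maxiter": 30})
        if not res.success:
            n_fail += 1
        if coarse_best is None or res.fun < coarse_best.fun:
            coarse_best = res
    if coarse_best is None or n_fail == len(starts) > cfg.max_restarts_without_convergence:
        raise RuntimeError("masked rigid registration did not converge")

    # stage 2: refine the best candidate on the full point set
    objective = make_objective(
        idx_all[::max(1, int(np.ceil(len(idx_all) / cfg.max_points)))])
    best = minimize(objective, coarse_best.x, method="Powell",
                    options={"xtol": cfg.xtol, "ftol": 1e-8, "maxiter": 60})
    T_inv = RigidTransform.from_params(best.x[:3], best.x[3:], center=center)
    T = T_inv.inverse()
    logger.info("masked_rigid_register: metric=%.5f rot=%.3f deg evals=%d",
                best.fun, T.rotation_angle_deg(), n_eval)
    return SuperimpositionResult(T, float(best.fun), mask, n_eval)
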