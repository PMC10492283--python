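"""Synthetic serial-CBCT phantom with known growth and known stable regions.

Each subject is a T1/T2 volume pair emulating the study conditions of the
real cohorts: an ellipsoidal "maxilla" (cortical shell, trabecular interior
with band-limited texture, palatal plate), four bright mini-screw cylinders
(1.6 mm diameter, 11 mm length) rigidly attached to a designated stable
core, a smooth spatially varying growth deformation whose masked magnitude
is calibrated to mean 1.8 mm / SD 0.6 mm, amplified to ~2.75 mm at a
posterior-inferior "tuberosity" pole and attenuated to exactly zero on the
stable core and screws, a random global rigid misalignment between T1 and
T2, and additive intensity noise.  Every quantity the pipeline estimates
(displacement field, stable region, global rigid transform, tooth
displacements) is returned as ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from .morphology import remove_small_components

from .core_io import BinaryMask, ImageVolume, LandmarkSet
from .fields import VectorField, _invert_vox, jacobian_determinant
from .registration import RigidTransform

logger = logging.getLogger("maxstab")

__all__ = ["PhantomSpec", "GroundTruth", "Baseline", "SubjectPair",
           "generate_baseline", "synthesize_growth", "cohort"]

TOOTH_NAMES = ("RU6", "LU6", "RU1", "LU1")


@dataclass
class PhantomSpec:
    """Parameters of the synthetic cohort.

    Axis convention: axis 0 = left-right (right positive), axis 1 =
    posterior-anterior (anterior positive), axis 2 = inferior-superior
    (superior positive).  All lengths in mm.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: float = 0.5          # isotropic voxel size; scaled up from the
                                  # clinical 0.4 mm so the 11 mm screws and a
                                  # proportioned maxilla fit a 96-voxel frame
    # anatomy
    semi_axes: tuple[float, float, float] = (16.0, 14.0, 11.0)
    shell_thickness: float = 1.2
    palate_z_offset: float = -4.0
    palate_thickness: float = 1.6
    intensity_background: float = 40.0
    intensity_trabecular: float = 320.0
    intensity_cortical: float = 650.0
    intensity_screw: float = 2800.0
    texture_sd: float = 80.0      # trabecular texture amplitude
    texture_smooth_vox: float = 1.5
    # mini-screws
    screw_diameter: float = 1.6
    screw_length: float = 11.0
    # stable core
    core_center_offset: tuple[float, float, float] = (0.0, -2.0, 2.5)
    core_radius: float = 4.2
    screw_freeze_pad: float = 1.0     # bone within this distance of a screw stays rigid
    attenuation_margin: float = 2.6   # width of the smooth 0->1 ramp outside the rigid set
    stable_ceiling: float = 1.2       # designated max true displacement of the stable region
    # growth field
    mean_displacement: float = 1.8    # target masked mean |displacement|
    sd_displacement: float = 0.6      # target masked SD
    pole_magnitude: float = 2.75      # "tuberosity" elongation, posterior-inferior
    pole_sigma: float = 5.0
    pole_center_offset: tuple[float, float, float] = (0.0, -13.0, -4.0)
    blob_sigma: float = 4.5           # band-limit of the random field (mm)
    # rigid perturbation between T1 and T2
    rotation_max_deg: float = 5.0
    translation_max_mm: float = 2.5
    # noise
    noise_sd: float = 25.0
    landmark_noise: float = 0.03      # annotation jitter, mm: screw landmarks
                                      # localise sub-voxel on the bright blobs
    # inter-subject anatomical variation (cohort only; subject 0 is canonical)
    anatomy_amplitude: float = 0.8
    anatomy_sigma: float = 6.4
    max_retries: int = 5

    def __post_init__(self) -> None:
        degenerate_ok = self.mean_displacement == self.sd_displacement == 0.0
        if not degenerate_ok and (self.mean_displacement <= self.sd_displacement
                                  or self.sd_displacement < 0):
            raise ValueError("require mean_displacement > sd_displacement >= 0 "
                             "(or both zero for a growth-free pair)")
        if not (self.screw_length > self.screw_diameter > 0):
            raise ValueError("require screw_length > screw_diameter > 0")

    @property
    def spacing3(self) -> np.ndarray:
        return np.full(3, float(self.spacing))

    @property
    def extent(self) -> np.ndarray:
        return (np.asarray(self.shape) - 1) * self.spacing

    @property
    def center(self) -> np.ndarray:
        return self.extent / 2.0


@dataclass
class GroundTruth:
    """Oracle quantities for one subject pair.

    ``true_field`` is the forward (T1 -> T2, rigid part removed)
    material-displacement field on the T1 grid; ``stable_mask`` the voxels
    whose true displacement is at most the configured stable ceiling;
    ``rigid`` the planted global rigid transform mapping the growth-deformed
    T1 frame into the T2 frame; ``tooth_displacements`` the exact 3-vector
    displacement (mm) of each tooth landmark in the T1 frame;
    ``subject_to_template`` the pullback field on the subject grid that maps
    subject points to their template (canonical) correspondents.
    """

    true_field: VectorField
    stable_mask: BinaryMask
    rigid: RigidTransform
    tooth_displacements: dict[str, np.ndarray]
    subject_to_template: VectorField | None = None


@dataclass
class Baseline:
    """Output of :func:`generate_baseline`; unpacks as (volume, landmarks, mask)."""

    volume: ImageVolume
    landmarks: LandmarkSet
    mask: BinaryMask
    geometry: "_Geometry | None" = None
    texture: np.ndarray | None = None

    def __iter__(self):
        return iter((self.volume, self.landmarks, self.mask))


@dataclass
class SubjectPair:
    subject_id: str
    t1: ImageVolume
    t2: ImageVolume
    landmarks_t1: LandmarkSet
    landmarks_t2: LandmarkSet
    maxilla_mask: BinaryMask
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# analytic geometry
# ---------------------------------------------------------------------------

def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


@dataclass
class _Geometry:
    """Canonical analytic scene, all in physical mm coordinates."""

    center: np.ndarray
    semi_axes: np.ndarray
    core_center: np.ndarray
    screw_segments: np.ndarray      # (4, 2, 3): [head, tip] per screw
    tooth_points: dict[str, np.ndarray]
    pole_center: np.ndarray
    pole_outward: np.ndarray
    spec: PhantomSpec

    def rho(self, pts: np.ndarray) -> np.ndarray:
        rel = (pts - self.center) / self.semi_axes
        return np.sqrt(np.sum(rel * rel, axis=-1))

    def mask_indicator(self, pts: np.ndarray) -> np.ndarray:
        return self.rho(pts) <= 1.0

    def dist_to_screw_axes(self, pts: np.ndarray) -> np.ndarray:
        """Min distance (mm) from each point to any screw axis segment."""
        d = np.full(pts.shape[:-1], np.inf)
        for head, tip in self.screw_segments:
            ab = tip - head
            denom = float(ab @ ab)
            t = np.clip(((pts - head) @ ab) / denom, 0.0, 1.0)
            proj = head + t[..., None] * ab
            d = np.minimum(d, np.linalg.norm(pts - proj, axis=-1))
        return d

    def rigid_set_distance(self, pts: np.ndarray) -> np.ndarray:
        """Distance to the rigid (frozen) set: core ball plus screw capsules."""
        d_core = np.linalg.norm(pts - self.core_center, axis=-1) - self.spec.core_radius
        d_scr = self.dist_to_screw_axes(pts) - (self.spec.screw_diameter / 2.0
                                                + self.spec.screw_freeze_pad)
        return np.maximum(np.minimum(d_core, d_scr), 0.0)

    def bone_value(self, q: np.ndarray, texture_at_q: np.ndarray,
                   screw_eval_pts: np.ndarray | None = None,
                   screw_segments: np.ndarray | None = None) -> np.ndarray:
        """Intensity of the scene: bone evaluated at ``q`` (canonical coords),
        screws evaluated at ``screw_eval_pts`` (subject coords)."""
        s = self.spec
        rho = self.rho(q)
        e = 0.4 / float(np.min(self.semi_axes))           # ~0.4 mm soft edge in rho units
        in_w = _smoothstep((1.0 - rho) / e)
        # texture-modulated shell thickness: an irregular cortical rim gives
        # the registration tangential signal along the surface
        tex_n = np.clip(texture_at_q / max(s.texture_sd, 1e-9), -2.0, 2.0)
        delta = (s.shell_thickness * (1.0 + 0.3 * tex_n)) / float(np.min(self.semi_axes))
        shell_w = in_w * _smoothstep((rho - (1.0 - delta)) / e)
        dz = np.abs(q[..., 2] - (self.center[2] + s.palate_z_offset))
        pal_w = in_w * _smoothstep((s.palate_thickness / 2.0 - dz) / 0.4)
        cort_w = np.maximum(shell_w, pal_w)
        val = (s.intensity_background
               + in_w * (s.intensity_trabecular - s.intensity_background + texture_at_q)
               + cort_w * (s.intensity_cortical - s.intensity_trabecular))
        pts = screw_eval_pts if screw_eval_pts is not None else q
        segs = screw_segments if screw_segments is not None else self.screw_segments
        geom_scr = _Geometry(self.center, self.semi_axes, self.core_center, segs,
                             self.tooth_points, self.pole_center, self.pole_outward, s)
        d = geom_scr.dist_to_screw_axes(pts)
        scr_w = _smoothstep((s.screw_diameter / 2.0 - d) / 0.2)
        return val * (1.0 - scr_w) + s.intensity_screw * scr_w


def _make_geometry(spec: PhantomSpec, rng: np.random.Generator) -> _Geometry:
    c = spec.center
    semi = np.asarray(spec.semi_axes, dtype=float)
    core = c + np.asarray(spec.core_center_offset)
    # four screws: axes near the left-right direction, tilted in distinct
    # planes so the eight head/tip landmarks span all three axes
    half = spec.screw_length / 2.0
    mids = core + np.array([[0.0, 2.5, 0.0], [0.0, -2.5, 0.0],
                            [0.0, 0.0, 2.5], [0.0, 0.0, -2.5]])
    # alternating axis directions spread the eight head/tip landmarks over
    # the whole core region and keep the screw bodies apart
    tilts = np.array([[np.cos(0.65), np.sin(0.65), 0.0],
                      [-np.cos(0.65), -np.sin(0.65), 0.0],
                      [np.cos(0.65), 0.0, np.sin(0.65)],
                      [-np.cos(0.65), 0.0, -np.sin(0.65)]])
    segs = np.empty((4, 2, 3))
    for i in range(4):
        ax = tilts[i] + rng.normal(0.0, 0.03, 3)
        ax /= np.linalg.norm(ax)
        segs[i, 0] = mids[i] + half * ax   # head
        segs[i, 1] = mids[i] - half * ax   # tip
    lo, hi = np.zeros(3), spec.extent
    if np.any(segs.reshape(-1, 3) < lo) or np.any(segs.reshape(-1, 3) > hi):
        raise ValueError("screws not placeable inside the volume extent")
    teeth = {
        "RU6": c + np.array([11.0, -4.0, -7.0]),
        "LU6": c + np.array([-11.0, -4.0, -7.0]),
        "RU1": c + np.array([1.2, 12.0, -5.5]),
        "LU1": c + np.array([-1.2, 12.0, -5.5]),
    }
    pole = c + np.asarray(spec.pole_center_offset)
    outward = (pole - c) / np.linalg.norm(pole - c)
    return _Geometry(c, semi, core, segs, teeth, pole, outward, spec)


def _grid_points(spec: PhantomSpec) -> np.ndarray:
    idx = np.indices(spec.shape, dtype=np.float32)
    return np.moveaxis(idx, 0, -1) * spec.spacing


def _sample_grid_field(grid_arr: np.ndarray, pts_mm: np.ndarray, spec: PhantomSpec,
                       order: int = 1) -> np.ndarray:
    coords = np.moveaxis(pts_mm, -1, 0) / spec.spacing
    return map_coordinates(grid_arr, coords, order=order, mode="nearest")


def _sample_vec(field_mm: np.ndarray, pts_mm: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    out = np.empty_like(pts_mm)
    for cdim in range(3):
        out[..., cdim] = _sample_grid_field(field_mm[..., cdim], pts_mm, spec)
    return out


def _smooth_noise(shape, sigma_vox: float, rng: np.random.Generator,
                  n_comp: int = 1) -> np.ndarray:
    out = np.empty((n_comp,) + tuple(shape), dtype=np.float32)
    for comp in range(n_comp):
        noise = rng.standard_normal(shape).astype(np.float32)
        sm = gaussian_filter(noise, sigma_vox)
        out[comp] = sm / max(float(sm.std()), 1e-9)
    return out[0] if n_comp == 1 else out


# ---------------------------------------------------------------------------
# growth field
# ---------------------------------------------------------------------------

def _build_growth_field(spec: PhantomSpec, geom: _Geometry, mask: np.ndarray,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Backward warp field w and forward field u (mm) on the grid.

    ``T2pre(y) = T1(y + w(y))`` and ``u = (id + w)^{-1} - id``.  The
    magnitude over the maxilla mask is calibrated so the *forward*
    displacement matches the configured mean/SD (an outer pass corrects the
    small distortion the inversion introduces); the stable set carries
    exactly zero; the pole region is driven inward by the pole magnitude so
    the forward motion there is outward elongation.
    """
    if spec.mean_displacement == 0.0 and spec.pole_magnitude == 0.0:
        zero = np.zeros(spec.shape + (3,), dtype=np.float32)
        return zero, zero.copy()
    pts = _grid_points(spec)
    sigma_vox = spec.blob_sigma / spec.spacing
    V = _smooth_noise(spec.shape, sigma_vox, rng, n_comp=3)
    Vmag = np.sqrt(np.sum(V * V, axis=0))
    # soft-normalised direction: stays smooth through zeros of V (magnitude
    # dips there instead of the direction flipping)
    eps = 0.5
    Vn = np.moveaxis(V, 0, -1) / np.sqrt(Vmag * Vmag + eps * eps)[..., None]

    # pole blend: backward field points inward at the pole so the forward
    # (material) displacement is an outward elongation
    d_pole = np.linalg.norm(pts - geom.pole_center, axis=-1)
    p = np.exp(-0.5 * (d_pole / spec.pole_sigma) ** 2).astype(np.float32)[..., None]
    W = _smoothstep(geom.rigid_set_distance(pts) / spec.attenuation_margin
                    ).astype(np.float32)[..., None]
    z = np.clip((Vmag - Vmag.mean()) / max(float(Vmag.std()), 1e-9), -2.5, 2.5)[..., None]

    # w = W [ (1-p) alpha exp(beta z) Vn - p pole n_out ]; alpha/beta solved
    # numerically so masked |w| hits the configured mean and SD; the
    # exponential profile stays positive and can compress the dispersion
    # down to the structural floor (attenuation ramp, direction dips, pole)
    pole_term = (W * p * spec.pole_magnitude) * (-geom.pole_outward)
    base = W * (1.0 - p) * Vn
    tgt = np.array([spec.mean_displacement, spec.sd_displacement])

    def build(al, be):
        return base * (al * np.exp(be * z)) + pole_term

    def stats(al, be):
        m = np.linalg.norm(build(al, be)[mask], axis=-1)
        return np.array([m.mean(), m.std()])

    def calibrate(goal, al, be):
        for _ in range(15):
            s0 = stats(al, be)
            if np.all(np.abs(s0 - goal) < 2e-3 * goal):
                break
            J = np.column_stack([(stats(al + 0.05, be) - s0) / 0.05,
                                 (stats(al, be + 0.05) - s0) / 0.05])
            try:
                step = np.linalg.solve(J, goal - s0)
            except np.linalg.LinAlgError:
                break
            al = max(al + float(step[0]), 0.05)
            be = float(np.clip(be + step[1], -1.5, 1.5))
        if abs(stats(al, be)[0] - goal[0]) > 0.05 * goal[0]:
            # dispersion unreachable for this draw: match the mean exactly
            be = 0.0
            al = al * goal[0] / stats(al, 0.0)[0]
        return al, be

    def invert(w):
        u_vox = _invert_vox(np.moveaxis(w, -1, 0) / spec.spacing, n_iter=40, tol=1e-2)
        return np.moveaxis(u_vox, 0, -1) * spec.spacing

    al, be = calibrate(tgt, spec.mean_displacement / 0.8, 0.2)
    w = _defold(build(al, be).astype(np.float32), spec)
    u = invert(w)
    # the inversion remaps magnitude over the deformed domain and inflates
    # the SD; one corrective pass lowers the backward-field SD goal
    sd_u = float(np.linalg.norm(u[mask], axis=-1).std())
    if abs(sd_u - tgt[1]) > 0.03 * tgt[1]:
        goal = np.array([tgt[0], float(np.clip(tgt[1] * tgt[1] / sd_u,
                                               0.5 * tgt[1], 1.2 * tgt[1]))])
        al, be = calibrate(goal, al, be)
        w = _defold(build(al, be).astype(np.float32), spec)
        u = invert(w)
    # scalar correction: pin the forward-field mean
    r = tgt[0] / max(float(np.linalg.norm(u[mask], axis=-1).mean()), 1e-9)
    if abs(r - 1.0) > 0.005:
        w = _defold((w * np.float32(r)).astype(np.float32), spec)
        u = invert(w)
    got = np.linalg.norm(u[mask], axis=-1)
    logger.info("growth calibration: alpha=%.3f beta=%.3f masked |u| mean=%.3f sd=%.3f "
                "(targets %.2f/%.2f)", al, be, float(got.mean()), float(got.std()),
                tgt[0], tgt[1])
    return w, u


def _defold(w_mm: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Locally smooth the field wherever id + w approaches folding."""
    for k in range(10):
        det = jacobian_determinant(VectorField(w_mm, spec.spacing3)).data
        if det.min() > 0.15:
            break
        bad = gaussian_filter((det < 0.3).astype(np.float32), 2.0)
        blend = np.clip(bad * 3.0, 0.0, 1.0)[..., None]
        sigma = 1.5 + 0.3 * k
        smooth = gaussian_filter(w_mm, (sigma, sigma, sigma, 0))
        w_mm = (1.0 - blend) * w_mm + blend * smooth
    det = jacobian_determinant(VectorField(w_mm, spec.spacing3)).data
    if det.min() <= 0:
        raise RuntimeError(f"growth field folds (min Jacobian {det.min():.3f})")
    return w_mm


def _point_inverse(w_mm: np.ndarray, pts: np.ndarray, spec: PhantomSpec,
                   n_iter: int = 30) -> np.ndarray:
    """Solve y + w(y) = pt per point; returns y."""
    pts = np.atleast_2d(pts).astype(np.float64)
    y = pts.copy()
    for _ in range(n_iter):
        y = pts - _sample_vec(w_mm, y.astype(np.float32), spec)
    return y


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def generate_baseline(spec: PhantomSpec, seed: int) -> Baseline:
    """Generate the canonical T1 volume, its landmark set and maxilla mask."""
    rng = np.random.default_rng(seed)
    geom = _make_geometry(spec, rng)
    texture = (_smooth_noise(spec.shape, spec.texture_smooth_vox, rng) * spec.texture_sd)
    pts = _grid_points(spec)
    tex_at = _sample_grid_field(texture, pts, spec)
    data = geom.bone_value(pts, tex_at) + rng.normal(0.0, spec.noise_sd, spec.shape)
    vol = ImageVolume(data.astype(np.float32), spec.spacing3)
    mask = BinaryMask(geom.mask_indicator(pts), spec.spacing3)
    lms = LandmarkSet()
    for i, (head, tip) in enumerate(geom.screw_segments, start=1):
        lms[f"screw{i}.head"] = head + rng.normal(0.0, spec.landmark_noise, 3)
        lms[f"screw{i}.tip"] = tip + rng.normal(0.0, spec.landmark_noise, 3)
    for name, p in geom.tooth_points.items():
        lms[f"{name}.{'mb_cusp' if '6' in name else 'incisal_mid'}"] = (
            p + rng.normal(0.0, spec.landmark_noise, 3))
    return Baseline(vol, lms, mask, geometry=geom, texture=texture)


def synthesize_growth(baseline: Baseline, spec: PhantomSpec, seed: int
                      ) -> tuple[ImageVolume, GroundTruth]:
    """Warp a baseline by a calibrated growth field plus a rigid perturbation."""
    if baseline.geometry is None:
        raise ValueError("baseline must come from generate_baseline")
    sub = _synthesize_subject(spec, baseline.geometry, baseline.texture, seed,
                              anatomy=None, subject_id="phantom")
    return sub.t2, sub.ground_truth


def cohort(spec: PhantomSpec, n_subjects: int, seed: int) -> list[SubjectPair]:
    """Generate ``n_subjects`` paired fixtures with a shared template anatomy.

    Subject 0 carries the canonical anatomy and serves as the template;
    later subjects add a smooth random anatomical variation whose exact
    subject-to-template correspondence is recorded in the ground truth.
    """
    if n_subjects < 2:
        raise ValueError("cohort requires n_subjects >= 2")
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2 ** 31 - 1, size=n_subjects)
    rng0 = np.random.default_rng(int(child_seeds[0]))
    geom = _make_geometry(spec, rng0)
    texture = _smooth_noise(spec.shape, spec.texture_smooth_vox, rng0) * spec.texture_sd
    subjects = []
    for s in range(n_subjects):
        rng_s = np.random.default_rng(int(child_seeds[s]) + 1)
        if s == 0:
            anat = None
        else:
            anat = (_smooth_noise(spec.shape, spec.anatomy_sigma / spec.spacing, rng_s, 3)
                    * spec.anatomy_amplitude)
            anat = np.moveaxis(anat, 0, -1).astype(np.float32)
        subjects.append(_synthesize_subject(spec, geom, texture, int(child_seeds[s]) + 2,
                                            anatomy=anat, subject_id=f"subj{s:02d}"))
    return subjects


def _synthesize_subject(spec: PhantomSpec, geom: _Geometry, texture: np.ndarray,
                        seed: int, anatomy: np.ndarray | None,
                        subject_id: str) -> SubjectPair:
    rng = np.random.default_rng(seed)
    pts = _grid_points(spec)

    # --- subject anatomy: bone warped by the anatomy field; rigid objects
    # (screws, stable core) shifted as a block so they stay truly rigid
    if anatomy is None:
        a_s = np.zeros(spec.shape + (3,), dtype=np.float32)
    else:
        a_s = anatomy
    scr_centroid = geom.screw_segments.reshape(-1, 3).mean(axis=0)
    tau = _anat_point_inverse(a_s, scr_centroid[None], spec)[0] - scr_centroid
    segs_s = geom.screw_segments + tau
    core_s = geom.core_center + tau
    teeth_s = {n: _anat_point_inverse(a_s, p[None], spec)[0]
               for n, p in geom.tooth_points.items()}
    geom_s = _Geometry(geom.center, geom.semi_axes, core_s, segs_s,
                       teeth_s, geom.pole_center, geom.pole_outward, spec)

    def subject_scene(y_pts: np.ndarray) -> np.ndarray:
        q = y_pts + _sample_vec(a_s, y_pts, spec)
        tex = _sample_grid_field(texture, q, spec)
        return geom.bone_value(q, tex, screw_eval_pts=y_pts, screw_segments=segs_s)

    t1_data = subject_scene(pts) + rng.normal(0.0, spec.noise_sd, spec.shape)
    mask_q = pts + _sample_vec(a_s, pts, spec)
    mask = BinaryMask(geom.mask_indicator(mask_q), spec.spacing3)

    # --- growth + rigid perturbation
    w = u = None
    for attempt in range(spec.max_retries):
        try:
            w, u = _build_growth_field(spec, geom_s, mask.data, rng)
            break
        except RuntimeError:
            logger.warning("%s: growth field folded, regenerating (attempt %d)",
                           subject_id, attempt + 1)
    if w is None:
        raise RuntimeError("could not generate a diffeomorphic growth field")

    ang = rng.uniform(0.4, 1.0) * spec.rotation_max_deg
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    tr_dir = rng.normal(size=3)
    tr_dir /= np.linalg.norm(tr_dir)
    trans = tr_dir * rng.uniform(0.4, 1.0) * spec.translation_max_mm
    from scipy.spatial.transform import Rotation
    G = RigidTransform.from_params(
        Rotation.from_rotvec(np.radians(ang) * axis).as_euler("xyz", degrees=True),
        trans, center=spec.center)

    # T2(z) = T1s(h), h = G^{-1} z + w(G^{-1} z)
    Ginv = G.inverse()
    y_h = pts @ Ginv.rotation.T + Ginv.translation
    h = y_h + _sample_vec(w, y_h.astype(np.float32), spec)
    t2_data = subject_scene(h.astype(np.float32)) + rng.normal(0.0, spec.noise_sd, spec.shape)

    true_field = VectorField(u, spec.spacing3)

    umag = np.linalg.norm(u, axis=-1)
    stable = mask.data & (umag <= spec.stable_ceiling)
    stable = remove_small_components(stable, 100)
    if not stable.any():
        raise RuntimeError("planted stable region is empty")
    stable_mask = BinaryMask(stable, spec.spacing3)

    # --- landmarks at T2: y' solves y' + w(y') = y*, then the rigid part
    lms_t1 = LandmarkSet()
    lms_t2 = LandmarkSet()
    tooth_disp: dict[str, np.ndarray] = {}
    for i, (head, tip) in enumerate(segs_s, start=1):
        for part, p in (("head", head), ("tip", tip)):
            # screws ride the rigid part only: the growth field is exactly
            # zero on the padded screw capsules by construction
            lms_t1[f"screw{i}.{part}"] = p + rng.normal(0.0, spec.landmark_noise, 3)
            lms_t2[f"screw{i}.{part}"] = G.apply(p) + rng.normal(0.0, spec.landmark_noise, 3)
    for name, p in teeth_s.items():
        suffix = "mb_cusp" if "6" in name else "incisal_mid"
        yp = _point_inverse(w, p[None], spec)[0]
        tooth_disp[name] = yp - p
        lms_t1[f"{name}.{suffix}"] = p + rng.normal(0.0, spec.landmark_noise, 3)
        lms_t2[f"{name}.{suffix}"] = G.apply(yp) + rng.normal(0.0, spec.landmark_noise, 3)

    gt = GroundTruth(true_field, stable_mask, G, tooth_disp,
                     subject_to_template=VectorField(a_s, spec.spacing3))
    t1 = ImageVolume(t1_data.astype(np.float32), spec.spacing3)
    t2 = ImageVolume(t2_data.astype(np.float32), spec.spacing3)
    logger.info("%s: masked true |u| mean=%.3f sd=%.3f, stable voxels=%d, rigid %.2f deg",
                subject_id, float(umag[mask.data].mean()), float(umag[mask.data].std()),
                stable_mask.n_voxels, G.rotation_angle_deg())
    return SubjectPair(subject_id, t1, t2, lms_t1, lms_t2, mask, gt)


def _anat_point_inverse(a_s: np.ndarray, pts: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Subject position of a canonical point: solve y + a_s(y) = pt."""
    return _point_inverse(a_s, pts, spec)
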