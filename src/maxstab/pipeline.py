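"""End-to-end pipeline drivers.

Chains the per-module operations into the three study stages:

1. discovery — screw-validated rigid alignment, deformable registration of
   every T1/T2 pair, transfer of displacement magnitudes to the template
   (cohort subject 0), and stability-atlas / NRS extraction;
2. application — reverse-mapping the NRS into a test subject's frame and
   masked rigid superimposition of its T1/T2 pair;
3. evaluation — 3D NRS versus simulated 2D cephalometric tooth-movement
   measurement and their ICC agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import BinaryMask, ImageVolume, LandmarkSet
from .fields import DisplacementFieldPair, VectorField, field_magnitude, warp_scalar
from .phantom import SubjectPair
from .registration import DemonsConfig, RigidTransform, apply_rigid, deformable_register, fit_rigid_landmarks
from .screw_validation import inter_screw_distances, screw_stability_report
from .stability_atlas import StabilityAtlas, build_atlas
from .superimposition import MaskedRigidConfig, SuperimpositionResult, masked_rigid_register, reverse_map_nrs
from .evaluation import (ReferenceFrame, ToothDisplacement, measure_tooth_displacement,
                         method_agreement, project_lateral, superimpose_2d)

logger = logging.getLogger("maxstab")

__all__ = [
    "PairRegistration", "register_pair", "validate_cohort_screws",
    "discover_atlas", "superimpose_subject", "evaluate_subject", "evaluate_cohort",
]


@dataclass
class PairRegistration:
    """Rigid screw alignment plus deformable registration of one T1/T2 pair."""

    screw_rigid: RigidTransform          # maps T2 points into the T1 frame
    t2_aligned: ImageVolume
    fields: DisplacementFieldPair        # forward: T1 -> aligned-T2 correspondence
    magnitude: ImageVolume               # |forward| on the T1 grid, mm


def register_pair(subject: SubjectPair, demons: DemonsConfig | None = None) -> PairRegistration:
    """Screw-based rigid alignment followed by diffeomorphic registration."""
    screws = [n for n in subject.landmarks_t1.names() if n.startswith("screw")]
    T = fit_rigid_landmarks(subject.landmarks_t2.subset(screws),
                            subject.landmarks_t1.subset(screws))
    t2a = apply_rigid(subject.t2, T, reference=subject.t1,
                      background=float(np.median(subject.t2.data)))
    pair = deformable_register(subject.t1, t2a, demons)
    return PairRegistration(T, t2a, pair, field_magnitude(pair.forward))


def aligned_true_field(subject: SubjectPair, screw_rigid: RigidTransform) -> VectorField:
    """Planted correspondence field of the rigidly *aligned* pair.

    The deformable stage registers T1 against T2 resampled with the
    estimated screw transform, so the field it should recover is the planted
    growth field composed with the residual of that alignment:
    ``u_eff(x) = (T_hat . G)(x + u(x)) - x`` where G is the planted global
    rigid transform and ``T_hat`` the estimated screw alignment (ideally
    ``G^{-1}``, up to landmark noise).
    """
    gt = subject.ground_truth
    E_inv = screw_rigid.compose(gt.rigid)
    fld = gt.true_field
    idx = np.indices(fld.shape, dtype=np.float64)
    pts = np.moveaxis(idx, 0, -1) * fld.spacing + fld.origin
    corresp = (pts + fld.data) @ E_inv.rotation.T + E_inv.translation
    return VectorField((corresp - pts).astype(np.float32), fld.spacing,
                       fld.origin, fld.direction)


def validate_cohort_screws(subjects: list[SubjectPair], alpha: float = 0.05):
    """Table-2-style report: paired t over the 12 inter-screw distances."""
    dist_pairs = [(inter_screw_distances(s.landmarks_t1),
                   inter_screw_distances(s.landmarks_t2)) for s in subjects]
    return screw_stability_report(dist_pairs, alpha=alpha)


@dataclass
class AtlasResult:
    atlas: StabilityAtlas
    registrations: dict[str, PairRegistration]
    template_id: str


def discover_atlas(subjects: list[SubjectPair], template_index: int = 0,
                   demons: DemonsConfig | None = None,
                   template_demons: DemonsConfig | None = None,
                   min_component: int = 100) -> AtlasResult:
    """Full discovery stage on a cohort.

    Each subject's T1/T2 displacement magnitude is estimated by
    :func:`register_pair`; subjects other than the template are brought to
    the template grid by a deformable T1-to-T1 registration, and the pooled
    magnitudes are graded into the stability atlas.
    """
    if len(subjects) < 2:
        raise ValueError("need >= 2 subjects")
    if template_demons is None:
        # inter-subject shape differences are smaller than growth; a lighter
        # schedule suffices for the magnitude transfer
        template_demons = DemonsConfig(iterations=(60, 40, 20))
    template = subjects[template_index]
    regs: dict[str, PairRegistration] = {}
    mags = []
    for s in subjects:
        reg = register_pair(s, demons)
        regs[s.subject_id] = reg
        if s is template:
            mags.append(reg.magnitude)
        else:
            t2s = deformable_register(template.t1, s.t1, template_demons or demons)
            mags.append(warp_scalar(reg.magnitude, t2s.forward))
        logger.info("discover_atlas: %s registered", s.subject_id)
    atlas = build_atlas(mags, template.maxilla_mask, min_component=min_component)
    return AtlasResult(atlas, regs, template.subject_id)


def superimpose_subject(subject: SubjectPair, nrs_template: BinaryMask,
                        subject_to_template: VectorField,
                        config: MaskedRigidConfig | None = None) -> SuperimpositionResult:
    """Reverse-map the NRS into the subject frame and align T2 to T1 over it."""
    nrs_subj = reverse_map_nrs(nrs_template, subject_to_template)
    res = masked_rigid_register(subject.t1, subject.t2, nrs_subj, config)
    return res


def evaluate_subject(subject: SubjectPair, nrs_subject: BinaryMask,
                     config: MaskedRigidConfig | None = None,
                     frame: ReferenceFrame | None = None,
                     ) -> tuple[list[ToothDisplacement], list[ToothDisplacement]]:
    """Tooth displacements of one subject under both superimposition methods.

    3D: masked rigid registration on the NRS; 2D: per-side lateral MIP
    cephalograms superimposed on the projected NRS, averaged over sides for
    each tooth's own side.  Right teeth are measured on the right
    projection, left teeth on the left.
    """
    frame = frame or ReferenceFrame()
    res3d = masked_rigid_register(subject.t1, subject.t2, nrs_subject, config)
    rec3d = measure_tooth_displacement(subject.landmarks_t1, subject.landmarks_t2,
                                       res3d.transform, frame, method="NRS-3D",
                                       subject_id=subject.subject_id)
    rec2d: list[ToothDisplacement] = []
    for side in ("right", "left"):
        ceph1 = project_lateral(subject.t1, side)
        ceph2 = project_lateral(subject.t2, side)
        ref = project_lateral(nrs_subject, side)
        t2d = superimpose_2d(ceph1, ceph2, ref.data)
        recs = measure_tooth_displacement(subject.landmarks_t1, subject.landmarks_t2,
                                          t2d, frame, method="Bjork-2D",
                                          subject_id=subject.subject_id)
        prefix = "R" if side == "right" else "L"
        rec2d.extend(r for r in recs if r.tooth.startswith(prefix))
    return rec3d, rec2d


def evaluate_cohort(subjects: list[SubjectPair], nrs_template: BinaryMask,
                    config: MaskedRigidConfig | None = None):
    """Table-3-style agreement table over a test cohort.

    The NRS is carried into each subject's frame through the generator's
    recorded subject-to-template correspondence (exact for phantom
    cohorts), isolating the measurement-concordance question from
    inter-subject registration error.
    """
    all3d: list[ToothDisplacement] = []
    all2d: list[ToothDisplacement] = []
    for s in subjects:
        nrs_subj = reverse_map_nrs(nrs_template, s.ground_truth.subject_to_template)
        r3, r2 = evaluate_subject(s, nrs_subj, config)
        all3d.extend(r3)
        all2d.extend(r2)
        logger.info("evaluate_cohort: %s measured", s.subject_id)
    table = method_agreement(all3d, all2d)
    return table, all3d, all2d
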