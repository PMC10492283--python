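# Methods

`maxstab` implements a pipeline for finding *natural reference structures*
(NRS) in the growing maxilla from serial 3D volume pairs anchored on
orthodontic mini-screws, and for using the discovered NRS to superimpose
new serial pairs so that tooth movement can be measured in a
growth-corrected frame.  Because the clinical image data behind the method
are not publicly deposited, the package ships a synthetic phantom whose
every planted quantity is returned as ground truth; all quantitative
claims the test suite makes are claims about recovery of planted signal,
not about clinical anatomy.

## Model and procedure

The core assumption is that four bone-anchored mini-screws (1.6 mm
diameter, 11 mm length) are positionally stable over the observation
interval, which is first verified statistically: the 6 head-to-head and 6
tip-to-tip inter-screw distances are compared between timepoints with
paired t tests (two-sided, df = n−1), reproducing the structure of the
published validation table.  Screws that pass act as fiducials.

Per subject, the follow-up scan (T2) is mapped into the baseline frame
(T1) in two stages:

1. **Rigid stage.** A least-squares rigid fit (Kabsch: SVD of the
   cross-covariance of centred landmark sets, with the determinant
   correction that forbids reflections) on the eight screw head/tip
   landmarks.
2. **Deformable stage.** A stationary-velocity log-demons registration.
   A velocity field v is updated with the symmetric Thirion force
   (intensity difference times the mean of fixed and warped-moving
   gradients, normalised so updates are bounded), smoothed with a fluid
   kernel (σ = 2.0 voxels on the update) and an elastic kernel (σ = 0.5
   voxels on the velocity), and exponentiated by scaling and squaring.
   Forward and backward displacement fields are exp(+v) and exp(−v), so
   they are mutually inverse up to interpolation error and the Jacobian
   determinant of id + field stays positive — the working proxy for
   diffeomorphic validity, checked after every run.
   The tracked similarity is a local correlation (5³ window) weighted by
   the fixed image's local variance, so structureless background does not
   dilute it; an update that would worsen the similarity is step-halved
   and ultimately rejected, which makes the per-level similarity trace
   monotone by construction.  Three pyramid levels with 100/70/60
   iterations; convergence when the relative improvement stays below 1e−5
   for 10 iterations.  These schedules were chosen for reliable recovery
   of smooth, growth-scale (≈2 mm) deformations at ≈0.5 mm voxels and are
   all exposed in `DemonsConfig`.

The per-voxel magnitude of the forward field is the *displacement
relative to the screws* — the quantity pooled across subjects.  Subjects
are brought to a common template (cohort subject 0 by default; the
published template-construction procedure is not public, and designating
one subject's baseline is the standard testable alternative) through a
deformable T1-to-T1 registration with a lighter schedule (60/40/20),
since inter-subject shape differences in the phantom are smaller than
growth.  Only scalar magnitudes are transferred; vector reorientation by
the warp Jacobian is deliberately out of scope because the grading uses
magnitudes alone.

**Grading.** With m and s the grand mean and sample SD of the pooled
magnitude over the maxilla mask, voxels are graded: level 1 (≤ m−s,
boundary inclusive), level 2 (m−s, m], level 3 (m, m+s], level 4 beyond.
Level-1 voxels, cleaned of connected components below 100 voxels and
closed with a radius-1 ball, form the NRS.  Under the planted study
conditions (m = 1.8 mm, s = 0.6 mm) the cuts are 1.2 / 1.8 / 2.4 mm.

**Superimposition.** For a new pair the template-space NRS is carried
into the subject frame with nearest-neighbour warping through the
template–subject correspondence, and a rigid transform is estimated by
maximising normalised cross-correlation evaluated *only at NRS voxels*.
The optimiser is derivative-free (Powell) over three Euler angles and
three translations (scaled 1° ≈ 1 mm) about the mask centroid, with a
two-stage multi-start: seven starts on a ~4000-voxel subsample, then
refinement of the best on up to 20 000 voxels.  A soft quadratic penalty
beyond ±15° / ±10 mm encodes that serial scans of one patient are
coarsely pre-positioned; scipy's hard-bounded Powell was measurably
unreliable on this objective, so the penalty replaces bounds.
Out-of-volume samples take a low constant so empty space cannot
correlate.

**Evaluation.** Lateral cephalograms are simulated by maximum-intensity
projection of the left or right half-volume along the left–right axis.
The classic 2D superimposition is emulated deterministically: a 2D rigid
fit of the two cephalograms over the projected NRS, which stands in for
manually traced stable structures.  Because the masked 2D similarity is
cheap but multimodal (a screw shadow can lock onto the wrong neighbour),
the fit sweeps the plausible repositioning range exhaustively (±8°,
±6 mm) before Powell refinement of the best cells.  Both images are
pre-smoothed by 1 pixel — with a reference patch of only a few hundred
pixels, raw projection noise otherwise creates spurious similarity
optima.  Tooth displacement is the
frame-projection of (transformed T2 landmark − T1 landmark), sagittal x
positive anterior and vertical y positive superior; right teeth are
measured on the right projection and left teeth on the left.  Agreement
per tooth-axis variable between the 3D and 2D paths is ICC(A,1) — the
two-way random-effects, absolute-agreement, single-measure intraclass
correlation computed from explicit ANOVA mean squares, with the F-based
95% CI (Satterthwaite degrees of freedom) — banded excellent ≥ 0.9,
good ≥ 0.75, moderate ≥ 0.5, else poor.  The same ICC implementation
serves the screw-validation module.

The reliability-study sample-size utility implements the
Walter–Eliasziw–Donner approximation (one-sided); at the published
configuration (ρ0 = 0.8, ρ1 = 0.95, α = 0.05, power 0.8, 2 raters) it
returns 13.  Published reliability formulas differ in sidedness and
rounding by a few subjects, so the utility is reported, not asserted
against any printed cohort size.

## The synthetic phantom

Each subject is a T1/T2 pair on a 96³ grid of 0.5 mm isotropic voxels
(48 mm field of view; the clinical voxel size is 0.4 mm, but an 11 mm
screw plus a proportioned maxilla and a repositioning margin do not fit a
38 mm frame, and the grid/spacing trade-off is a phantom parameter).  The
scene is analytic: an ellipsoidal "maxilla" (semi-axes 16/14/11 mm) with
a cortical shell whose thickness is modulated by the trabecular texture
field — an irregular rim gives surface-tangential registration signal —
a palatal plate, band-limited trabecular texture (SD 80 intensity units,
1.5-voxel correlation), four bright screw cylinders, and additive
Gaussian noise (SD 25).  Because T2 is rendered by evaluating the
analytic scene at back-transformed coordinates, both timepoints are
equally sharp and carry independent noise — no cumulative interpolation
blur, and no asymmetric smoothing that would bias similarity optima.

The growth field is constructed backwards (the warp w used to render T2)
and inverted numerically (damped fixed point) to obtain the forward
material displacement u returned as ground truth.  w is a band-limited
random direction field (soft-normalised so directions stay smooth through
zeros), magnitude-shaped as α·exp(βz) in a standardised band-limited
scalar z, attenuated *exactly to zero* on the rigid set (the stable-core
ball, radius 4.2 mm, plus the padded screw capsules) with a 2.6 mm
smoothstep ramp, and blended at a posterior-inferior surface pole into an
outward elongation of 2.75 mm (the "tuberosity").  α and β are solved
numerically so the masked |w| hits mean 1.8 mm / SD 0.6 mm; a second pass
corrects the SD goal for the inflation the inversion introduces, and a
final scalar rescale pins the masked forward mean to 1.80 mm exactly.
The achieved forward SD lands at 0.63–0.74 mm across seeds: the
attenuation ramp and the Jacobian re-weighting of the inversion set a
structural floor the shaping cannot cross.  Folding is repaired by local
re-smoothing wherever the Jacobian determinant of id + w approaches zero;
fields that cannot be repaired are regenerated (bounded retries).  The
planted stable region reported as ground truth is the set of mask voxels
whose true displacement does not exceed the stable ceiling (1.2 mm),
cleaned of small components.

T2 adds a global rigid misalignment (rotation up to 5°, translation up to
2.5 mm, about the volume centre — patient repositioning between visits)
applied after the growth warp; screws and landmarks ride it exactly.
Landmark annotation jitter is 0.03 mm (screw landmarks localise
sub-voxel on bright blobs).  Cohorts share one template anatomy; subjects
beyond the first receive a smooth random anatomical variation field
(amplitude 0.8 mm) whose exact subject-to-template correspondence is
recorded, with screws, core and teeth carried as a rigid block so implant
geometry stays exact.  Tooth landmarks (first-molar mesiobuccal cusps,
central-incisor edge midpoints) sit near the anterior/inferior surface,
outside the stable core, so they move with growth; their exact
displacements are solved per point.

What the phantom does *not* emulate: beam hardening, scatter and metal
artefacts, anatomical detail beyond the ellipsoid-plus-plate caricature,
growth fields with the spatial structure of real maxillary remodelling,
or inter-subject variation beyond a smooth warp.  Passing tests therefore
demonstrate that the pipeline recovers planted displacement structure,
thresholds, stable regions and rigid motions under CBCT-like noise and
texture — not that the anatomical regions reported for patients would be
reproduced.

## Numerical choices and degenerate inputs

- Displacement convention: corresponding point = physical point +
  displacement, mm, on axis-aligned grids; fields stored as 4D NIfTI with
  the vector dimension last.  Voxel indices never cross module
  boundaries.
- Field inversion: damped fixed point (λ = 0.5), contractive for
  displacement-gradient norms up to 3; tolerance 0.01 voxel.
- Scaling and squaring halts when the scaled velocity is below half a
  voxel; composition uses linear interpolation with edge clamping.
- Grading boundaries are right-closed (level 1 includes its cut).  A
  constant pooled field yields degenerate thresholds (SD 0), flagged
  rather than raised.
- Identical rater columns return ICC exactly 1.0; an all-constant rating
  matrix is degenerate (no between-subject variance to agree about).
  Zero-variance paired differences give t = ±∞ (p = 0) for a non-zero
  mean and t = 0 (p = 1) otherwise.
- A phantom spec with zero growth, zero rigid range and zero noise
  renders T2 identical to T1 — the degenerate identity case used by
  tests.
- Masked rigid registration refuses masks under 50 voxels; NRS extraction
  raises when no level-1 voxels survive cleanup.

## Problem sizes

The shipped study conditions are a five-subject discovery cohort at 96³
(matching the published grading statistics 1.8 ± 0.6 mm) and a
fifteen-subject evaluation cohort at 64³ over the same 48 mm field of
view, with the NRS resampled between the grids; the evaluation carries
the NRS into each subject through the generator's recorded
subject-to-template correspondence, isolating measurement concordance
from inter-subject registration error (which the discovery stage
exercises separately).  Both cohorts are regenerated from seeds at test
time; nothing is stored on disk.

## Known limitations

- The demons magnitude recovery is biased low by ~8–10% (regularisation
  and the surface aperture problem); recovered grading cuts inherit part
  of this bias but stay well within 15% of the planted values after
  pooling.
- The 2D path inherits a genuine physical error of the cephalometric
  method: out-of-plane components of the repositioning rotation displace
  projected landmarks by up to ~0.5 mm at 5°, which is visible in the 2D
  columns of the agreement table exactly as it would be clinically.
- Whole-volume rigid registration is implemented only as the comparison
  baseline for the regional-superimposition claim; scaling/affine
  transforms and multi-modal similarity metrics are out of scope.
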