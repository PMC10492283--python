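# maxstab

Voxel-wise stability atlasing and regional superimposition of the growing
maxilla from serial 3D volumes.

## The problem

Measuring how teeth move during orthodontic treatment of a growing patient
requires superimposing the follow-up scan on the baseline scan — but in an
adolescent the whole maxilla remodels, so there is no obvious fixed frame.
Classic 2D cephalometry solves this with Björk's manually traced "stable
reference structures"; in 3D no validated equivalent existed.  The approach
implemented here uses temporarily implanted orthodontic mini-screws as
fiducials: after verifying statistically that the inter-screw geometry is
constant across the interval, every maxillary voxel's displacement
*relative to the screws* is measured by diffeomorphic registration, pooled
across subjects on a shared template, and graded.  Voxels that barely move
form the **natural reference structures (NRS)** — anatomy that can replace
the screws as a registration reference in patients who have none.

For users: orthodontic/craniofacial imaging researchers who want a fully
scriptable, reproducible version of this pipeline, with a synthetic phantom
that provides ground truth for every stage.

## The method in brief

Per subject pair (T1 baseline, T2 follow-up):

1. **Screw validation** — the 12 inter-screw distances (6 head–head,
   6 tip–tip over 4 screws) compared between timepoints with paired t
   tests, *t* = d̄ / (s_d/√n), df = n−1.
2. **Rigid alignment** — least-squares (Kabsch) fit on the 8 screw
   head/tip landmarks.
3. **Deformable registration** — stationary-velocity log-demons with
   scaling-and-squaring exponentiation: forward/backward fields
   φ_f = exp(+v), φ_b = exp(−v), positive Jacobian throughout.
4. **Stability atlas** — per-voxel magnitudes ‖φ_f‖ transferred to a
   template, averaged, and graded by the grand mean m and SD s into four
   levels with cuts m−s, m, m+s; cleaned level-1 voxels are the NRS.
   At the study conditions m = 1.8 mm, s = 0.6 mm, so the cuts are
   1.2 / 1.8 / 2.4 mm.
5. **Regional superimposition** — the NRS is reverse-mapped into a new
   subject's frame and a rigid transform is fitted over NRS voxels only.
6. **Evaluation** — tooth movements (sagittal x, anterior-positive;
   vertical y, superior-positive) measured under the 3D NRS
   superimposition and under a simulated 2D lateral-cephalogram
   superimposition, compared with the absolute-agreement intraclass
   correlation ICC(A,1).

Because the underlying clinical images are not publicly deposited, the
package includes a first-class synthetic cohort generator
(`maxstab.phantom`) with known growth fields, known stable regions, known
rigid misalignments and known tooth displacements; see `docs/methods.md`.

## Worked example

```python
import numpy as np
from maxstab.phantom import PhantomSpec, cohort
from maxstab.pipeline import discover_atlas

subjects = cohort(PhantomSpec(), n_subjects=5, seed=1)     # ~3 min
result = discover_atlas(subjects)                          # ~10 min
thr = result.atlas.thresholds
print(f"pooled displacement: mean {thr.mean:.3f} mm, SD {thr.sd:.3f} mm")
print(f"stability cuts: {thr.cut1:.2f} / {thr.cut2:.2f} / {thr.cut3:.2f} mm")
nrs = result.atlas.nrs.data
core = subjects[0].ground_truth.stable_mask.data
print(f"NRS Dice vs planted stable core: "
      f"{2 * np.sum(nrs & core) / (nrs.sum() + core.sum()):.2f}")
```

prints (seed 1):

```
pooled displacement: mean 1.671 mm, SD 0.508 mm
stability cuts: 1.16 / 1.67 / 2.18 mm
NRS Dice vs planted stable core: 0.73
```

The planted growth has masked mean 1.80 mm and SD ≈ 0.65 mm, so the
recovered statistics show the expected mild regularisation bias of the
deformable registration (≈ 7% low) while the grading cuts stay within a
few percent of the planted 1.2 / 1.8 / 2.4 mm and the extracted NRS
overlaps the planted stable region with Dice 0.73.

A command-line interface mirrors the library:

```bash
maxstab phantom --n 5 --seed 42 --out cohort/
maxstab validate-screws --cohort cohort/ --out screws.csv
maxstab atlas --cohort cohort/ --template subj00 --out atlas/
maxstab evaluate --cohort cohort/ --atlas atlas/ --out agreement.csv
```

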