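# Methods

`multiatlas` implements multi-atlas segmentation (MAS) of female-pelvis CT
with four atlas-selection strategies and evaluates them end-to-end on a
synthetic phantom cohort.  This note records the models, the tunable
parameters that matter, the numerical choices, and what the synthetic
experiments do and do not establish.

## The pipeline

MAS segments an uncontoured target image in three steps: *select* a
shortlist of n contoured atlases, *register* each shortlisted atlas to the
target with deformable image registration (DIR), *fuse* the propagated
contours by per-voxel majority vote (ties fall to background).  The
strategies differ only in the selection step:

| strategy | candidate pool    | ranking score                                   | registrations per target |
|----------|-------------------|--------------------------------------------------|-----------|
| cMAS     | all N atlases     | post-DIR normalized cross-correlation (NCC)      | N         |
| SAGA     | target's volume-feature subgroup | post-DIR NCC within the subgroup  | subgroup size |
| FASA     | all N atlases     | Euclidean distance D between normalized volume-feature vectors (low first) | n |
| SIM      | all N atlases     | mutual information after rigid alignment (high first) | n |
| random   | all N atlases     | seeded uniform draw (baseline)                   | n         |

Default n = 5 fused atlases, balancing fusion quality against registration
cost.  All rankings break ties by lexicographic atlas id, so every strategy
is deterministic given its seed.

## Volume features, normalization, subgrouping

The feature vector of a subject is its per-structure contour volume in cc,
by default over (body external, bladder, rectum, left/right femoral head,
bone marrow); the structure list is configurable because evaluation uses
only the five organs.  Because bladders span hundreds of cc and femoral
heads tens, each structure is min–max scaled to [0, 1] over the *atlas set*
(the only affine map achieving exactly those bounds on the fitting set); a
constant column is a degenerate-feature error.  The identical affine map is
applied to the target, deliberately unclamped so out-of-range targets stay
ordered in distance ranking.

Subgrouping partitions the atlas library by k-means (Lloyd) on the
normalized vectors, minimizing the within-cluster sum of squared distances.
Lloyd is implemented here directly so its policies are exactly the
documented ones: initialization from k distinct data points by seeded
sampling, 10 restarts keeping the lowest objective, at most 300 iterations,
and empty-cluster repair by re-seeding the centroid from the point farthest
from its current centroid (keeps k fixed).  scikit-learn's KMeans serves as
an independent cross-check in the tests, never as the implementation.
Default k = 4 on a ~70-atlas library (≈18 per subgroup); the scaled-down
acceptance experiment uses k = 3 on 20 atlases so the expected subgroup
size (~7) stays above n = 5.  A target is assigned to the subgroup with the
nearest centroid, ties to the lowest cluster index.

Target volumes are taken as given inputs (ground truth in the synthetic
experiments); estimating a target's organ volumes before segmentation
exists is an open problem deliberately out of scope.

## Registration stand-in

The clinical experiments behind this design used a commercial hybrid engine
(RayStation ANACONDA) whose internals are proprietary; this package
substitutes an open stand-in with a stated contract, and **no
registration-dependent number is expected to match the clinical tables**.

*Rigid*: multi-resolution (downsampling factors 4, 2, 1) Powell search over
three Euler angles (degrees) and three translations (mm) maximizing mutual
information of the overlap.  MI uses a plain 32-bin joint histogram with
equal-width bins over each image's observed range — ranking, not absolute
MI, is what the pipeline consumes.  Deterministic; if the evaluation budget
is hit the best-found transform is returned with `converged=False`.

*Deformable*: a free-form displacement field held on a coarse control grid
(default spacing 16 mm) and expanded to the image grid by separable cubic
B-spline tensor products.  Cost = mean squared intensity difference (valid
because atlas and target are same-modality CT) + 1e-3 × the squared second
differences of the control coefficients (bending energy).  Optimization is
multi-resolution gradient descent with backtracking line search; only
cost-decreasing steps are accepted, and the returned field is guaranteed
never to worsen the full-resolution MSD relative to its initialization
(falling back to the initialization if it would).

*Flat-region extrapolation*: intensity-driven registration observes
displacement only where the image has gradient; on piecewise-constant
phantoms the optimizer leaves homogeneous interiors near zero.  A final
normalized-convolution step extrapolates the field from gradient-rich
voxels into flat ones (gradient-magnitude-weighted Gaussian averaging,
sigma 16 mm), blending so well-observed voxels keep their optimized values.
The step is skipped if it would break the MSD-never-worse contract.

Labels propagate through the total field (rigid ∘ free-form) by
nearest-neighbour pull-back; points leaving the atlas volume become
background.

What the stand-in does *not* do: ANACONDA's anatomically constrained
(contour-guided) objective, Parzen-windowed MI, STAPLE or locally weighted
fusion.

## Evaluation

DSC = 2|A∩B| / (|A|+|B|) with exact integer arithmetic.  95HD extracts
surface voxels (6-connectivity; the image border counts as background),
computes directed nearest-surface distances both ways with a k-d tree,
pools the two directed sets, and returns the 95th percentile (linear
interpolation between order statistics) in cm.  The pooled-symmetric
convention (not max of two directed percentiles) was chosen where the
verbal definition supports either; the tests pin it against an O(n²)
brute-force oracle.  Strategy comparisons use the two-tailed paired t-test
at 0.05 (scipy behind the interface, textbook formula as the test oracle);
no multiple-testing correction is applied, mirroring single-threshold
reporting — a known limitation.

## Synthetic cohort: the stated world

No public dataset accompanies the clinical study, so every stage runs on
procedurally generated phantoms (default grid 96×96×64 at 2 mm isotropic —
small enough for desk-scale registration, large enough for distinct
structures; acquisition geometry was never stated clinically and is a free
choice here):

* body = elliptic cylinder (soft tissue ≈ 40 HU-like), bladder = ellipsoid
  (≈ 10), rectum = curved tube (≈ 30), femoral heads = spheres (≈ 700),
  bone marrow = paired columns (≈ 200), air background −1000, additive
  Gaussian noise (sd 10 by default).  Intensities are CT-plausible
  constants, not calibrated HU; the similarity metrics only need consistent
  contrast.
* every organ is voxelized by bisecting the threshold of its analytic
  distance function until the realized volume matches the request —
  comfortably inside the 5% contract (typically <1%).
* cohort volumes are drawn uniformly per subject: bladder 70.89–437.09 cc
  and rectum 21.3–115.04 cc (the clinical cohort's ranges), femoral heads
  20–30 cc and marrow 25–40 cc (plausible defaults, stated once here).
* inter-subject deformation = sum of seeded Gaussian radial-basis bumps
  (sigma 30 mm), amplitude = 10 mm × the subject's (bladder+rectum) cc
  deviation from the cohort's lower bounds, normalized by the maximal
  deviation.  Large-volume subjects are therefore also the strongly
  deformed ones: pairwise volume mismatch and pairwise deformation
  magnitude correlate **by construction**, which is the premise that makes
  selection-strategy comparisons meaningful.  Amplitudes stay well below
  the bump sigma, keeping the maps diffeomorphic in practice.

Two consequences of the piecewise-constant intensity model are worth
stating plainly.  First, a 32-bin joint histogram cannot separate the
soft-tissue classes (10/30/40 HU-like fall in one ~53-HU bin), so on
*noise-free* phantoms MI ranking is degenerate; with the default noise it
is not, and the insensitivity of MI to organ-volume differences that
remains is precisely the failure mode of intensity-based selection the
feature-based strategies are designed to fix.  Second, dense displacement
is unobservable inside homogeneous regions (the aperture problem), which
is why the deformable stand-in carries the flat-region extrapolation step
and why warp-recovery accuracy is assessed against the cohort's own
radial-basis deformation model rather than an arbitrary global field: a
global sinusoid's surface-tangential component is invisible to *any*
intensity-driven method on such phantoms.

A green synthetic test therefore establishes internal consistency of the
pipeline and the directional claims (feature-aware selection beats
intensity/random selection when volume mismatch drives registration
difficulty); it does not establish clinical DSC/95HD levels, which depend
on real anatomy, a real registration engine, and real intensity texture.

## Experiment protocol

The cohort splits into atlas library and held-out test set per fold
(re-randomized rather than rotated, matching the re-randomized three-fold
protocol; 30% test by default).  The normalizer and subgroups are fitted on
the atlas library only — the leakage guard in the acceptance tests asserts
bitwise invariance to test-set changes.  Deformable registrations are
cached per (target, atlas) and shared across strategies (SAGA's subgroup
lies inside cMAS's register-all pool), while each strategy's *logical*
registration count is recorded to preserve the cost profile.  Wall-clock
timings are logged but are never an acceptance surface.  Per-(target,
strategy) failures are recorded and the run continues; a strategy that
produces no results at all aborts the run.

## Known limitations

* The registration stand-in is far simpler than clinical engines; absolute
  DSC/95HD values on phantoms do not transfer to patients.
* GMM-based subgrouping is not implemented: the normative description is
  the k-means objective with nearest-centroid assignment, and k-means is
  what this package provides (the same interface could host a GMM later).
* No DICOM/DICOM-RT support; NIfTI-1 plus a JSON label-name sidecar only.
* No multiple-testing correction in the statistical summary.
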