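# Methods

## Overview

The package compares two ways of expressing a post-treatment maxillary
digital model (MDM) in the pre-treatment (T1) coordinate space:

* **Reference route** — the acquisition pose of the post-treatment scan is
  either known (a supplied transform, standing for a validated voxel-based
  CBCT superimposition treated as a black box) or recovered by registering
  the dental-crown regions onto a reference surface already in T1 space.
  Its output plays the role of the "T2" model.
* **Palatal (MDM) route** — the post-treatment scan is registered onto T1
  by its palatal-vault stable region after a landmark-seeded coarse
  alignment.  Its output is the "T2'" model.

Both models are measured with the same tooth landmarks (carried from T2 to
T2' by per-crown rigid registration), and the signed differences T2' − T2
of tooth position and orientation quantify the accuracy of the palatal
route; repeated runs with re-randomized operator noise quantify its
reliability.

## Rigid registration

Superimposition is strictly rigid: dental models are 1:1 replicas, so no
scale is estimated, and reflections are rejected in every solve.

**Landmark seeding.**  ≥3 non-collinear paired landmarks, matched by name,
give the closed-form least-squares rotation via SVD of the cross-covariance
(Kabsch), with the sign of the smallest singular direction flipped if
needed so det R = +1.  Collinear or under-determined configurations raise
a degenerate-configuration error rather than returning a bad fit.  When
source and destination points are bitwise identical the exact identity is
returned, so a null alignment stays null to the last bit downstream.

**Region-restricted trimmed ICP.**  The moving region is sampled at its
vertices plus face barycentres (edge midpoints are added for sparse masks;
a configurable cap of 6000 samples bounds run time, with a seeded
subsample if exceeded).  Nearest points on the fixed mesh are exact
point-to-triangle projections; candidate triangles come from a KD-tree
over triangle centroids (k = 12 nearest), which is reliable for the
near-uniform meshes used here.  Per iteration:

1. correspondences farther than `gate_factor` (default 5) times the
   previous trimmed RMS are rejected (guards against boundary capture);
2. the worst `trim_fraction` (default 10%) of the remainder is discarded
   (robustness to soft-tissue edge effects);
3. two candidate rigid updates are formed — a linearized point-to-plane
   Gauss-Newton step (signed distances along target normals, exact
   re-orthogonalization of the incremental rotation) and the closed-form
   fit onto the projections — and whichever lowers the trimmed RMS is
   accepted.  If neither does, iteration stops.

The accepted-step rule makes the trimmed RMS non-increasing by
construction while retaining point-to-plane's fast tangential convergence;
pure projection ICP stalls on the smooth vault (sliding modes converge
only linearly with a rate near 1).  Convergence is declared when the
relative RMS change drops below `tol` (default 1e-6) or after `max_iter`
(default 100) iterations; a trimmed RMS at machine zero returns the seed
unchanged, so self-registration is exactly the identity.  A near-planar
sample covariance (smallest/largest eigenvalue < 1e-6) sets a warning
flag, since in-plane pose is then weakly constrained.

## Measurement frame and tooth metrics

The functional occlusal plane (FOP) is the total-least-squares plane
(smallest-covariance-eigenvector normal) through the cusp points of the
bilateral first/second premolars and first molars, the molars'
distal-lingual cusps excluded — 14 points by default, all cusps of those
teeth taken literally; the normal is oriented toward the palatal suture
point B so angle signs are reproducible.  Suture points A (anterior) and
B (posterior) project to A', B' on the FOP; the frame is origin B',
x = unit(B'→A'), y = unit(B'→B) (= the FOP normal), z = x × y.  In frame
coordinates +x is anterior, +y gingival and +z transverse (toward the
patient's right in the phantom's convention).

Per tooth, the mesiodistal plane passes through the mesiodistal landmark
pair (central-groove points for molars, incisal-edge endpoints for
incisors) and their FOP projections; the buccolingual plane is
perpendicular to both the mesiodistal plane and the FOP, anchored at the
tooth-axis midpoint (the anchor does not affect angles).  The tooth axis
joins the buccal-groove points (molar) or the gingival- and incisal-edge
midpoints (incisor), oriented gingival → occlusal.

**Torque** is the signed angle between the axis projected onto the
mesiodistal plane and the FOP normal; **tip** the same with the
buccolingual plane.  This assignment is implemented literally even though
conventional orthodontic usage often swaps the two names for incisors; a
`swap_tip_torque` flag relabels them.  Sign conventions are fixed as
follows, since signed deviations require signed angles: the projected axis
is re-oriented to the gingival side of the FOP (angles are between
undirected lines and lie in (−90°, 90°)), and the in-plane reference
tangent is oriented along the frame +x axis for torque and +z for tip,
falling back to the other axis when nearly perpendicular (this makes the
convention well-defined for incisors, whose mesiodistal direction is
transverse).

**Crown transfer.**  The crown patch of the reference-route model is
rigidly registered onto T2' (seeded by the known relative pose of the two
aligned copies) and the tooth landmarks move with it.  Both routes are
therefore measured with identical landmark identifications, and when the
two models coincide the transfer is exactly the identity — landmark-picking
error cancels in the route comparison by construction.

## Statistics

Signed deviations are palatal-route minus reference-route (T2' − T2)
componentwise; `total` is the Euclidean norm of (dx, dy, dz).  Accuracy
uses the two-sided one-sample t-test of each deviation against zero
(scipy), α = 0.05, with no multiple-testing correction — deliberately
matching the single-test-per-variable design being emulated; a zero-variance
sample reports an undefined p (NaN) rather than a fabricated one.

Reliability uses the intraclass correlation computed from the Shrout-Fleiss
two-way ANOVA mean squares:

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1) MSE + (k/n)(MSC − MSE))
    ICC(3,1) = (MSR − MSE) / (MSR + (k−1) MSE)

Default is ICC(2,1) (two-way random effects, absolute agreement, single
measurement), configurable to ICC(3,1).  Raters in perfect agreement yield
exactly 1; vanishing between-subject variance emits a warning.  The ICC is
computed in-package (the formula is a dozen lines and must accept 2×2
matrices); `pingouin`'s ANOVA implementation serves as the independent
cross-check in the test suite.  ICCs are computed on frame coordinates
(x, y, z per tooth), pairing examiner 1's first session with the repeat
session (intra) and with examiner 2 (inter), for both routes.

## Synthetic phantom

The phantom replaces patient scans and defines the study conditions.

* **Palatal dome** — a parametric vault (34 mm wide, 40 mm long, 12 mm
  high) with an asymmetric anteroposterior profile, three transverse
  rugae ridges (1.2 mm) anteriorly and a median raphe ridge (0.5 mm)
  along the suture.  These anatomically motivated features matter: a
  near-elliptic smooth dome is almost rotationally symmetric, leaving the
  palatal registration weakly constrained about the vertical axis.  The
  stable-region mask covers the medial band of the most posterior ruga and
  the vault dorsal to it.
* **Crowns** — molars as subdivided boxes with four unequal cusp bumps
  (the asymmetry disambiguates pose), incisors as slabs pinched to an
  incisal edge with a slight twist.  Crowns are analytic solids, not
  anatomical scans, so landmark coordinates are exact by construction —
  which scanned anatomy cannot provide and which the closure tests
  require.  The default incisors sit 12 mm apart (a deliberate separation
  margin so independent random treatment motions cannot grossly collide);
  gross interpenetration after treatment still raises a geometry error.
* **Landmarks** — per-crown landmark sets, suture points A/B, two lateral
  stable points used (with A, B) to seed registration, and 14 FOP cusp
  points, exactly coplanar in the noiseless phantom (premolar cusps are
  emitted as landmark inputs only; premolars carry no mesh crowns).
* **Acquisition model** — per-tooth rigid treatment motions, a rigid
  global pose for the T2 scan, and independent Gaussian surface-noise
  draws along vertex normals for the T1 scan, the T2 scan and the
  reference surface (default 0.05 mm outside the stable region; the
  stable region's own noise is separately configurable, default 0,
  expressing the stable-region assumption literally).  An optional smooth
  low-frequency "soft-tissue drift" of the palate stresses that
  assumption.
* **Cohorts** — per-subject anatomy jitter (dome size ±5%, tooth
  positions σ = 0.5 mm, angles σ = 2°), random per-tooth treatment
  motions (≤6°, ≤2 mm by default) and random acquisition poses (≤8°,
  ≤4 mm), all inside the ≤10°/≤5 mm envelope the registration is
  validated for.  All randomness flows through seeded generators; a fixed
  seed reproduces meshes bit for bit.

Ground-truth tooth measurements are computed analytically from the phantom
parameters and landmark coordinates — never from the meshes — with the
ground-truth angle computation written independently of the measurement
module, so generator/measurer closure is a genuine two-route check.

**Noise injections and what they mean.**  Scan-surface noise perturbs
meshes only (landmarks are analytic), so it stresses registration.
Landmark-identification noise is injected on landmark coordinates only, at
two places in the validation: `landmark_noise_sd` perturbs the
palatal-route measurements once per subject, giving the accuracy-deviation
distribution a known scale that the report tables must recover; the
per-repeat operator noises (`repeat_noise_sd_mdm`, default 0.15 mm;
`repeat_noise_sd_reference`, default 0.02 mm) are re-drawn per reliability
run and express that the soft-tissue route is less repeatable than the
reference route.  With every noise at zero and identity motions the
validation report is exactly degenerate: all deviations 0.0, all ICCs 1.0.

## What the phantom does and does not show

Passing tests on the phantom demonstrate the pipeline's numerical
correctness: exact transform recovery in the noise-free limit,
insensitivity of the stable-region registration to tooth movement,
measurement closure, and correct statistical summarization of injected
error distributions.  The phantom does not model real anatomical shape
variation (no statistical shape model), cast defects or bubbles, actual
soft-tissue remodeling, CBCT reconstruction artifacts, or true operator
behaviour — so phantom results bound the method's algorithmic error, not
its clinical error.

## Problem sizes and numerical choices

Default meshes: 64×44 palate grid plus four 3x-subdivided crown boxes,
≈ 8 500 faces per model; the palatal mask yields ≈ 4 000 ICP samples.
Validation cohorts use 20 subjects (10 with three reliability repeats);
the injected-noise recovery study uses 200 subjects per noise level.
These sizes give sampling error comfortably inside the tolerances checked
(SD recovery to 15% needs n ≫ 1/(2·0.15²) ≈ 22).

Numerical conventions collected in one place: vertex deduplication on STL
read is exact-equality (not tolerance welding) to keep landmark-to-surface
distances stable; plane fits are orthogonal least squares; identical point
sets short-circuit to the exact identity in Kabsch and ICP; angle
degeneracies (axis perpendicular to a projection plane, suture
perpendicular to the FOP, coincident landmark pairs) raise errors rather
than returning NaN; the one-sample t refuses zero-variance input.

## Known limitations

* The crown-transfer seed uses the known relative pose of the two aligned
  copies; with real data from independent software the seed would come
  from a landmark pre-alignment and would converge more slowly.
* Point-to-surface queries use k-nearest centroid candidates; extremely
  non-uniform triangle sizes could in principle miss the true nearest
  triangle (not the case for the meshes generated here).
* The FOP cusp points, suture points and crown landmarks are inputs:
  automatic landmark detection on raw scans is out of scope.
* The voxel-based CBCT superimposition itself is represented as a given
  transform, not re-implemented; DICOM I/O and iso-surfacing are out of
  scope.
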