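# Methods

This note documents the models, conventions and numerical choices behind
`caninemko`, and what the synthetic evaluation does and does not
demonstrate.

## The kinematic model

The right pelvic limb is modelled as a chain of three rigid segments —
pelvis, femur (thigh) and tibia (crus) — connected by two spherical
(ball-and-socket) joints at the hip joint centre (HJC) and stifle joint
centre (SJC). Each segment carries an anatomical frame (AF) with x
cranial, y proximal and z lateral, and a *marker template*: the local AF
coordinates of its skin markers captured in a standing calibration.

Frames are built from 12 anatomical landmarks (iliac crests, ischial
tuberosities, greater trochanter, femoral epicondyles, fibular head,
tibial crests, malleoli) plus two cranial-thigh tracking markers:

* **pelvis** — origin mid-way between the iliac crests; x from the
  ischial midpoint toward the iliac midpoint; z lateral along the
  left-to-right iliac direction, orthogonalized against x.
* **femur** — origin mid-way between the epicondyles; y toward the
  greater trochanter; z lateral in the plane of the origin, GT and
  lateral epicondyle.
* **tibia** — origin mid-way between the malleoli; y toward the midpoint
  of fibular head and proximal tibial crest; z lateral through the
  lateral malleolus.

These axis recipes are this package's own reconstruction of the commonly
used canine segment-frame recommendations; they are fixed project-wide
and exercised by equivariance tests (a rigid motion of the laboratory
moves every frame by exactly that motion and leaves templates unchanged).

The medial epicondyle and medial malleolus markers exist only during
calibration; dynamic trials track 4 markers per segment.

## Joint centres

**Predicted (marker-only) centres.** The HJC is predicted in the pelvic
AF: its x (craniocaudal) and z (lateromedial) coordinates come from two
independent linear regressions on pelvic width *w* (iliac-crest marker
distance) and pelvic length *l* (iliac midpoint to ischial midpoint),
`coord = c0 + cw·w + cl·l`, fitted by ordinary least squares. Because no
canine coefficient table is published, the package ships defaults fitted
to its own synthetic training population of 24 virtual pelves
(width/length scales uniform in [0.85, 1.15], 2 mm anatomical noise);
real applications must supply their own coefficients. The y
(proximodistal) coordinate is minus the unsigned distance of the greater
trochanter from the *posterior pelvic plane*, the total-least-squares
plane through the four pelvic landmarks: the hip centre lies ventral to
that plane at trochanter depth. The SJC is predicted as the femoral AF
origin (epicondyle midpoint), i.e. exactly (0, 0, 0) in femoral
coordinates.

**Reference (bone-derived) centres.** Given bone-surface point clouds,
the HJC is the centre of the orthogonal-distance best-fit sphere to the
femoral head, and the SJC is the "centroid" of the best-fit cylinder to
the bilateral condyles. A cylinder is infinite, so its centroid is
defined here as the axis point at the midpoint of the projected extent
of the input cloud. Both fits minimize squared orthogonal distances
(geometric cost), with an algebraic solution as initializer for the
sphere and a spherical-angle axis parameterization for the cylinder
(seeded by the expected flexion-axis direction, solved by
Levenberg–Marquardt, 1e-10 relative cost tolerance, 200-iteration cap).

Every joint centre is stored in the AFs of *both* adjacent segments; the
two expressions must agree in the laboratory frame at calibration to
1e-9 mm (a validated model invariant).

## Pose estimation

**Single-body optimization (SO).** Per frame and per segment, the
weighted Procrustes problem

  min over (R, t) of  Σᵢ wᵢ ‖R pᵢ + t − qᵢ‖²

is solved in closed form (weighted Kabsch SVD with a reflection guard:
the smallest singular direction is sign-flipped when the determinant is
negative). Segments are independent; no joint constraint exists, so any
rigid component of soft tissue artefact (a common translation/rotation
of a whole marker cluster) passes directly into the estimated pose.

**Multibody kinematics optimization (MKO).** The chain is parameterized
in 12 minimal coordinates: pelvis translation (3, mm) and orientation
(3, Cardan z-x-y degrees), femur rotation about the HJC (3) and tibia
rotation about the SJC (3). Forward kinematics places the femur so that
its HJC expression coincides with the pelvis-side HJC, and likewise for
the tibia at the SJC — the spherical constraints hold *by construction*
(no constraint equations, no drift). Per frame, Levenberg–Marquardt
minimizes the weighted sum of squared distances between model-determined
and measured markers over the 12 coordinates (finite-difference
Jacobian, relative step 1e-6; convergence at 1e-10 relative cost change;
200-iteration cap; non-converged frames are flagged, never silently
returned). Frame 0 is initialized from the SO solution projected onto
the chain (rotational coordinates exact, joint-gap translations
discarded); subsequent frames warm-start from their predecessor.
Occluded markers drop out of the residual; a frame needs at least three
visible markers per segment (SO) or six spanning the chain (MKO).

**Joint angles.** Hip angles decompose `R_pelvisᵀ R_femur`, stifle
angles `R_femurᵀ R_tibia`, as intrinsic (body-fixed) z-x-y Cardan
angles — flexion/extension about z, adduction/abduction about the
rotated x, internal/external rotation about the twice-rotated y, i.e.
`R = Rz(α) Rx(β) Ry(γ)`. At |β| = 90° the decomposition is singular;
the toolkit raises an error rather than silently picking a convention
(canine gait keeps |β| small), and the tracker warns beyond |β| = 80°.

**Marker weighting.** The *local marker displacement* of a marker is the
time-mean distance of its measured position from its mean position, both
expressed in the segment's SO-estimated frame over a trial. Weights are
its reciprocal, floored at 0.5 mm (so a near-rigid marker cannot
dominate) and normalized to mean 1 (so weighted and unweighted costs are
comparable). Because SO frames themselves absorb part of any marker
offset — entirely so for rigid cluster motion — this metric
systematically underestimates the true artefact; it is a practical
surrogate, not a measurement of soft tissue artefact magnitude.

## Gait-cycle analysis and statistics

Paw contact is detected from the dorsal foot marker as the downward
zero-crossing of its fore–aft velocity (cranial-most excursion on a
treadmill), after zero-phase 2nd-order Butterworth low-pass filtering at
6 Hz. Joint-angle series are linearly resampled to 101 points per
contact-to-contact cycle (0–100 %, endpoints included); cycles shorter
than 10 frames are rejected with a warning.

Agreement between an estimated and a reference waveform is reported as:
Bland–Altman bias (mean difference) and CI (here the half-width of the
95 % limits of agreement, 1.96·SD of the differences; the confidence
half-width of the bias itself is selectable); R² from ordinary
regression of test on reference; and RMSD. Bias/CI/R² pool a subject's
cycles; RMSD is computed per cycle and averaged per subject. Paired
between-condition comparisons gate the test on Shapiro–Wilk normality of
the differences at α = 0.05: paired t when normality is not rejected,
Wilcoxon signed-rank otherwise; all-zero differences short-circuit to a
flagged degenerate result.

## The synthetic cohort

No canine marker/fluoroscopy dataset is distributable, so the package
evaluates itself on a seeded virtual cohort sized to a ~19 kg medium
dog (iliac-crest separation 80 mm at scale 1, femur ≈ 150 mm):

* **Subjects** — the standing-calibration layout is anisotropically
  scaled (width and length scales uniform in [0.85, 1.15]) and each
  landmark jittered by 1.5 mm SD placement noise.
* **Gait script** — treadmill walking at 0.7 m/s with a 0.7 s stride.
  Hip and stifle Cardan waveforms are fundamental + second-harmonic
  sinusoids rescaled to exact default flexion/extension ranges of 30°
  (hip) and 40° (stifle); out-of-sagittal ranges are ≤ 10°; the pelvis
  oscillates mildly about its calibration pose. Seeds individualize
  phases and harmonic mixing without changing the ranges.
* **Ground truth** — forward kinematics of the subject's own
  12-coordinate chain; true joint angles are the generalized
  coordinates themselves. Trials record a 10 % stride lead-in/out so
  every paw contact is an interior, detectable event.
* **Soft tissue artefact** — per segment, a *rigid* component (one
  gait-locked sinusoid of cluster rotation about the marker-cluster
  centroid plus cluster translation, expressed in the segment frame)
  and, per marker, a *non-rigid* sinusoid along a fixed random local
  direction; plus isotropic Gaussian measurement noise (0.3 mm SD).
  Default amplitudes follow the thigh > crus > pelvis ordering of
  canine skin mobility: rigid rotation (6, 1.5, 2)° and translation
  (4, 3, 1.5) mm on the thigh, roughly half that on the crus and a
  quarter on the pelvis; non-rigid amplitudes 2 / 1 / 0.8 mm. True
  canine artefact spectra are not published; these presets are
  stand-ins with a realistic ordering and magnitude, not measurements.

## The simulation studies

* **Constrained vs unconstrained tracking** (8 subjects × 3 cycles at
  100 Hz, full artefact): per-subject flexion/extension RMSD of MKO vs
  SO, compared with the gated paired pipeline. The rigid artefact
  component is precisely what separates the two estimators, so the full
  artefact model is used.
* **Hip-centre sensitivity** (20 trials): each trial is tracked twice on
  identical data, with the generating centres and with the HJC displaced
  by 16.7 mm — the scale of a landmark-regression prediction error —
  along a per-trial isotropic random direction (a real error's direction
  is subject-specific and unknown a priori). This is a one-factor
  sensitivity analysis, so trials carry the non-rigid artefact and
  measurement noise but not the randomized rigid component: a random
  rigid cluster motion is itself equivalent to a random bone-geometry
  perturbation and confounds the factor under study. With the full
  artefact model the mean degradation persists but its per-trial sign is
  partially masked by that interaction (exposed via `sta_preset="full"`).
* **Marker weighting** (20 trials, thigh non-rigid artefact ×3): MKO
  with uniform weights vs displacement-reciprocal weights on identical
  data. The same one-factor logic applies: the displacement metric can
  only observe the non-rigid component, so the study's default preset is
  non-rigid + noise.

Problem sizes (8 subjects, 20 trials, 3 cycles at 100 Hz) are the
package's desk-scale defaults: large enough for the paired tests to
resolve the multi-degree flexion/extension effects, small enough to run
a full evaluation in minutes on one core.

## What passing tests show — and what they do not

The synthetic cohort shares the real experiment's structure (marker set,
segment chain, gait ranges, artefact ordering) but not its physics: the
artefact is a low-order sinusoid model, not measured skin motion;
anatomy is an analytic layout, not CT; the reference standard is exact
ground truth, not fluoroscopic registration with its own ~1° / ~1 mm
error. Passing therefore demonstrates correctness of the estimators and
the *direction* of the method effects (constraints help sagittal-plane
accuracy; centre errors and poor weighting hurt), not the numeric error
levels to be expected on real dogs.

## Known limitations

* Spherical joints only: no hinge, parallel-mechanism or deformable
  stifle models, hence null articular translations by construction.
* Right-limb convention; left limbs would require mirroring, which is
  out of scope.
* No gap filling: occluded markers are dropped per frame, and frames
  below the visibility minimum are flagged invalid.
* Gimbal lock raises rather than re-parameterizes; series crossing
  |adduction| = 90° cannot be decomposed in this convention.
* The shipped hip-centre regression coefficients are synthetic-trained
  defaults for testing and simulation, not clinical values.
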