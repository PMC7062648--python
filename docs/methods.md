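# Methods

`scoliosim` estimates axial compressive forces in the spines of adolescents
with idiopathic scoliosis (AIS) during upright standing, with and without
carried loads. The pipeline runs from per-vertebra biplanar radiographic
landmarks to a subject-specific rigid-body trunk model, resolves the muscle
redundancy by static optimization, and reports intersegmental compressive
forces around the curve apex relative to an undeformed comparator and to the
unloaded condition. A synthetic-cohort generator stands in for patient
radiographs so the whole pipeline is testable without clinical data.

## Coordinate conventions

Right-handed global frame: x anterior, y superior, z subject's left.
Sagittal plane x–y, frontal plane z–y; the two radiographic planes share the
calibrated y axis. Vertebral orientation is a body-fixed Z–X–Y sequence
(flexion/extension about z, lateral bending about x, axial rotation about
y); angles are degrees at every interface. A left-convex curve deviates
toward +z.

## Geometry from landmarks

Nine points are digitized per vertebra T1–L5: four body corners per plane
and the frontal spinous-process point. Planar orientations are the mean of
the upper- and lower-corner line angles. Vertebral height is measured
between the centroids of the proximal and distal intervertebral disc spaces
in the sagittal plane (H_sagittal, with the vertebra's own endplate
centroids as fallback at the spine ends) and corrected for the out-of-plane
projection error as H_total = H_sagittal / cos(frontal tilt) — the unique
correction that restores a tilted segment's true length from its sagittal
projection. The frontal *body* tilt is used for this correction (not the
disc-centroid line), one of two defensible readings.

Axial rotation is a geometric surrogate: asin(spinous-process lateral offset
from the frontal body centre / nominal pedicle-to-spinous depth), with the
depth defaulting to 40 mm scaled linearly by stature. The radiographic
workflow this replaces fits a referential anatomic mesh per vertebra; the
surrogate is unbiased by construction on synthetic data but carries no
vertebra-shape information.

The Cobb angle is the maximal absolute frontal-tilt difference over all
superior–inferior vertebra pairs (the maximizing pair are the end
vertebrae); the apex is the vertebra with maximal lateral deviation from the
T1–L5 chord strictly between the end vertebrae, ties broken caudally.
Because the Cobb estimate is a maximum over pairs, landmark noise biases it
slightly upward (≈ +0.4° at 0.5 mm noise, measured by Monte-Carlo in the
test suite) — a known property of maximal-pair Cobb measurement, not an
implementation artifact.

## Synthetic cohorts

The generator emulates a 24-patient cohort of mild-to-moderate AIS: age 13.8
(SD 1.8) y, stature 161.2 (12.3) cm, mass 47.5 (8.0) kg, Cobb 22.1 (4.4)°,
11:13 left:right convexity, 21:3 female:male, apices T7–L1 with mid-thoracic
levels most frequent. Draws are truncated normals (±3 SD, physiologic
floors; truncated rather than rejected so n stays fixed).

The frontal curve is a single structural curve: a derivative-of-Gaussian
lateral-tilt profile centred on the apex (width 4 levels), scaled so the
discrete end-vertebra tilt difference equals the requested Cobb angle
exactly. Axial rotation couples to the curve with a Gaussian profile peaking
at the apex (default 0.3° per degree of apical tilt) directed so the spinous
process deviates toward the concavity. The sagittal profile is a
piecewise-cosine kyphosis (default 30° T1–T12) and lordosis (default 45°
L1–L5), drawn per subject with SD 6°; the "flat thoracic profile" subgroup
arises naturally for kyphosis below ~25°. Vertebral centres are the chained
integration of per-level heights along the per-level orientations (nominal
heights 18–28 mm scaled by stature).

Landmark synthesis is the exact inverse of the extraction: endplate corner
lines encode the plane angles exactly, the facing corner pairs of adjacent
vertebrae are symmetric about the shared disc node, and the spinous point
encodes the axial surrogate. This is a stylized projection model — it
ignores the cross-plane coupling a true cone-beam projection of a 3D-rotated
box would show — and it is what makes the zero-noise round trip exact to
numerical precision. Isotropic Gaussian noise (default SD 0.5 mm per
coordinate, the scale of manual digitization error) is added per landmark.
Consequently, passing round-trip tests demonstrate the internal consistency
of the extraction formulas, not robustness to real projection physics.

## The trunk model

Rigid bodies: pelvis (carrying the lumped lower limbs), sacrum, vertebrae
L5–T1, a lumped head+neck segment, two arms suspended at scapula attachment
points, and one soft-tissue carrier per trunk level (rib-cage mass over
T1–T12, abdominal mass over L1–L5). Seventeen 3-DOF intervertebral joints
run T1/T2–L5/S1, each placed at the disc node below its cranial vertebra
with axes from the caudal vertebra's orientation. Segment masses follow a
configurable anthropometric fraction table (head+neck 8 %, arms 5 % each,
thorax 20 %, abdomen 12 %, pelvis+sacrum 15 %, lower limbs 35 % lumped into
the pelvis support path); carriers hold 70 % of each trunk slice at a
modest anterior offset (3 %/2 % of stature, thoracic/lumbar), so relaxed
standing is close to sagittally balanced — with strongly anterior trunk
masses a dorsally angled backpack force cancels extensor demand instead of
engaging the abdominal muscles, which inverts the load-carrying response.

Subject-specific construction follows four steps: (1) scale by stature and
body mass, (2) impose the measured per-vertebra 3D orientations, (3) set
intersegmental joint distances from the measured (projection-corrected)
vertebral heights, (4) re-neutralize the head+neck, arms and carriers so
their global orientation is upright over the deformed column. Bushing
neutral poses are reset to the deformed reference angles, so passive moments
are identically zero in every simulated (neutral-pose) condition; the linear
stiffness defaults (1.5/1.7 N·m/° flexion/lateral) therefore never influence
results, which the test suite asserts. The undeformed twin keeps the
anthropometric scaling and measured vertebral heights, zeroes the frontal
and axial deviations, and restores the default sagittal alignment (whether a
comparator should instead keep the subject's own sagittal profile is an open
choice; the default-alignment reading makes the comparison sensitive to the
subject's measured sagittal shape, which is what produces sub-100% apex
ratios for flat thoracic profiles).

### Muscle and passive elements

Fascicles are straight lines between attachment points with maximum force
Fmax = CSA × 100 N/cm² (a uniform maximal muscle stress). The set needed to
make a fully articulated 3-DOF-per-joint chain solvable is larger than the
paraspinal core, because every joint needs local authority in all three
axes:

* **ES** — 17 erector-spinae fascicles per side from a sacral origin to each
  level T1–L5 (posterior 2.8 %, lateral 2.2 % of stature; 3.8 % lateral at
  thoracic levels where the iliocostalis runs on the rib angles). Straight
  chords, deliberately: on a deformed spine the chord strays from the curved
  column, and that inefficiency is the mechanism by which the deformity
  costs muscular effort and raises apical compression.
* **MF** — multifidus-like fascicles spanning three levels from each origin
  T1–L3 (caudal-most insert on the sacrum).
* **RA / EO / IO** — rectus abdominis and oblique sheets from the pelvis to
  rib carriers (T8/T10/T12).
* **TR** — trapezius-like fascicles from the scapula points to T1–T8: the
  muscular path that routes shoulder loads into the spine.
* **PS / QL** — psoas-like and quadratus-lumborum-like per-level lumbar
  fascicles: without a per-level lumbar flexor and lateral bender the
  lordotic demand profile is infeasible.
* **IC** — intercostal-like single-joint fascicles between adjacent
  carriers: local flexion/lateral authority in the thorax.
* **LD** — a latissimus-like shoulder-to-pelvis sling per side, the wide
  moment-arm antagonist for one-sided carrying.

Fascicle CSA scales with body mass (demands scale with mass × stature,
moment capacity with CSA × stature, so mass scaling keeps strength relative
to demand independent of anthropometrics). The per-group CSA defaults were
chosen once so that every condition in the study envelope — apex T7–L1, Cobb
up to the +3 SD draw, all four carrying modes at up to 20 % BW, extreme
anthropometric combinations — is feasible; infeasibility is an error by
design, never a softened fit.

Two passive element families complete the model. Axial-rotation reserve
actuators (one per joint, optimal moment 25 N·m) absorb axial moments
cheaply, standing in for passive axial resistance; their optimal moment is
deliberately large because single-shoulder loads induce axial demands of
tens of N·m, and an expensive reserve would force unphysiologic
co-contraction. Rib-cage struts — bidirectional force elements between
adjacent carriers at the mid-axillary line over the "true rib" levels T1–T7,
quadratic cost with a 500 N optimal force — transmit sustained one-sided
bending the way the bony cage does: as push–pull structural pairs with
near-zero net axial force, something a pull-only muscle set cannot do. They
are restricted to the upper cage so that deformity-related demands around
typical apex levels stay muscle-borne.

## Static optimization

At the reference pose the required moment at every joint dof equals minus
the moment of gravity and external loads on all bodies superior to the
joint. Muscle activations a ∈ [0, 1] minimize Σa² + Σ(reserve/25 N·m)² +
Σ(strut/500 N)² + Σ(support/10 kN)² under exact per-dof equilibrium plus six
whole-body equations balanced by support actuators (four foot points in
standing; thorax and pelvis contacts in prone, where gravity acts along the
body's +x axis). Force–length and force–velocity properties are not
modeled.

The solver maximizes the Lagrangian dual of this box-constrained QP by a
semismooth Newton iteration with an Armijo line search, then polishes the
active set with exact KKT solves on the free variables, reaching equality
residuals near machine precision (accepted solutions must satisfy 1e-6 N·m;
typical residuals are below 1e-10). A feasibility-seeded SQP fallback guards
rare hard instances, and an `InfeasibleError` naming the worst dof is raised
when no bounded solution exists. The procedure is deterministic: identical
inputs give identical outputs.

## Loads, reactions and reporting

Carried loads are point forces at the scapula attachment points (lateral
third of the shoulder girdle: ±6.5 % of stature lateral, 2 % posterior of
T3): backpack 20° dorsally angled split equally between sides, frontpack 25°
ventrally angled split equally, sidepack 5° dorsal + 10° lateral
(away from the midline — the hanging-outside-the-shoulder reading) at the
single concave- or convex-side point; magnitudes 10/15/20 % of body weight
with g = 9.81 m/s² exactly.

Joint reactions sum gravity, external, support, muscle and strut forces on
the chain superior to each joint; the axial compressive component is the
projection on the caudal vertebra's local superior axis (not the global
vertical), positive in compression — this projection is exactly what makes
the deformed-versus-undeformed comparison nontrivial. "Level" maps to the
joint immediately caudal to the named vertebra. Unloaded compressions are
expressed as percentages of the undeformed twin; loaded compressions as
percentages of the unloaded condition, at the apex and one and two levels
above and below. Because multi-level muscles terminate at specific vertebrae
and the local axes tilt, the compression profile shows local reversals of a
few percent along an overall caudally increasing trend; strict per-joint
monotonicity holds only for the gravity share.

Cohort statistics: means with sample SD (n−1), medians with IQR = Q3 − Q1
(linear-interpolation quartiles), two-sided Wilcoxon signed-rank tests
against 100 % (exact subset-sum null distribution with midranks up to n=25,
tie- and continuity-corrected normal approximation above; zero differences
dropped), and Pearson correlations (t transform, n−2 df). No
multiple-testing correction is applied. Undefined ratios (zero concave-side
denominator) are reported as NaN sentinels and excluded from cohort
summaries.

## Study sizes and determinism

The default study is 24 subjects × 15 static solves (unloaded AIS and twin,
4 carrying modes × 3 loads, prone), about 360 QP solves, completing in well
under a minute on one CPU; the test suite and the acceptance script each run
it once from a fixed or supplied seed, and reruns are bit-identical.

## Known limitations

* The muscle set and attachment geometry are a minimal parametric
  abstraction, not a validated anatomical model; absolute forces are
  indicative only, and percentage comparisons are the intended output.
* With a pull-only fascicle set, any one-sided moment is bought at a
  compression cost of roughly demand/moment-arm. Concave-side carrying —
  whose moment must be countered across the thoracolumbar spine — is
  therefore the costliest mode here, whereas richer models with full
  shoulder-girdle and rib-cage force paths find front and convex-side
  carrying highest. The backpack-lowest ordering and the
  deformity/monotonicity findings are robust across seeds; the
  concave-vs-convex ordering is a known structural limitation.
* A dorsally angled load slightly *unloads* the upper-thoracic extensors; in
  a narrow window this relief can exceed the added direct weight, producing
  sub-1 % decreases of upper-curve compression between 10 and 15 % BW for a
  few flat-profile subjects, so the loading response is monotone per subject
  except for these near-ties.
* The virtual CT scan is insensitive on this fascicle table: with one
  fascicle per group, side and level, mid-plane crossing only flips under
  extreme tilts, so convex/concave CSA ratios are 1.0 for almost every
  synthetic subject (fine-grained fascicle sets in imaging-validated models
  resolve the few-percent asymmetries this cannot).
* Shear components, intervertebral translations, facet/ligament structures,
  wrapping surfaces, postural adaptation to load, and motion-driven
  simulation are all out of scope; simulations are valid at the neutral
  reference pose only.
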