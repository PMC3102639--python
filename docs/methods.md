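# Methods

## Coordinate frame and sign convention

All landmarks live on one axial CT slice in a patient-centred frame:
`x` increases toward the patient's **left**, `y` toward the patient's
**posterior**, both in millimetres, origin arbitrary. The frame matters only
for the sign of angles: **right vertebral rotation is positive**, realized
as the anterior aspect of the vertebra turning toward the patient's right.
A right rotation by θ is the clockwise map
`(x, y) → (x cos θ + y sin θ, −x sin θ + y cos θ)` about the pivot.

Angle arithmetic is done in raw double precision; rounding to 0.1° (angles),
2 decimals (r, ICC) and 3 decimals (p) happens only at report formatting.

## The two measurements

**Anterior component (β, pedicle-base chord).** The two posterior points of
the vertebral body just beneath the pedicles define a chord;
β = −atan2(Δy, Δx) with Δ = left − right, the signed angle between the
chord and the horizontal axis. Coincident points are a degenerate-landmark
error.

**Posterior component (α, Ho's lamina bisector).** Each lamina inner
surface is an *ordered* segment (posterior end → anterior end); the order is
part of the data and removes the two-fold ambiguity of a bisector of
undirected lines. With unit directions û_L, û_R, the bisector is
b = (û_L + û_R)/‖û_L + û_R‖ and α = atan2(−b_x, −b_y), the signed angle
between the bisector and the vertical axis. Antiparallel directions
(‖û_L + û_R‖ < 1e−9) are a degenerate-bisector error.

**Torsional deformity.** τ = β − α, exactly, positive when the anterior
component leads toward the convex (right) side. The subtraction order is
fixed by the observed phenomenon: in right thoracic curves the vertebral
body rotates further right than the arch, so the typical τ is positive.

Angles at or beyond ±90° are rejected as annotation errors rather than
wrapped: an axial vertebral slice cannot be a quarter-turn rotated, so such
values always indicate mislabelled or swapped landmarks.

Both measurements are invariant under translation and uniform scaling and
equivariant under global rotation (each shifts by exactly the applied
angle), so τ is invariant under all three — patient positioning in the
gantry shifts α and β together but cannot change the torsion. These are
tested as exact (1e−9°) properties.

## Phantom model

The template is a mirror-symmetric landmark set with plausible thoracic
dimensions: pedicle-base points at (±15, 10) mm, lamina segments
(±3, 42) → (±16, 28) mm, canal centre (0, 25) mm. Symmetry forces
(α, β, τ) = (0, 0, 0).

A phantom with parameters (θ_post, τ) rotates the pedicle-base pair rigidly
by θ_post + τ and the four lamina endpoints by θ_post, both about the canal
centre — the minimal landmark-level realization of a gradual torsion between
vertebral body and posterior arch. Intra-component bending or asymmetric
remodelling of the body is deliberately not modelled. With zero noise the
measured triple equals (θ_post, θ_post + τ, τ) to machine precision;
component rotations are restricted to ±45°.

Annotation noise is isotropic Gaussian displacement of each of the six
landmarks (σ in mm). Because the angles are smooth functions of the
landmarks, sub-millimetre noise propagates almost linearly and leaves the
measured torsion approximately unbiased (verified at σ = 0.5 mm: mean
measured τ within 0.2° of truth over 10 000 replicates).

## Cohort and observer simulation

Per-subject (θ_post, τ, Cobb) are drawn from a trivariate normal. Defaults
are the study conditions of the motivating cohort: n = 25 adolescent
patients with structural right thoracic curves, θ_post ~ 7.9 ± 6.3°,
τ ~ 6.1 ± 3.9°, Cobb ~ 56.5 ± 11°, corr(τ, Cobb) = 0.36,
corr(τ, θ_post) = 0 and corr(θ_post, Cobb) = 0. The Cobb sd of 11° is a
modelling choice: only the mean (56.5°) and range (33–77°) are reported for
the reference cohort, and mean ± 2 sd reproduces that range. Under the
default independence of τ and θ_post, the anterior rotation β = θ_post + τ
has mean 14.0° and corr(τ, β) = σ_τ/√(σ_τ² + σ_θ²) ≈ 0.526 — both used as
closed-form oracles in the tests. Requested correlation pairs are checked
for positive semidefiniteness of the implied covariance before sampling.

Observer error is modelled on **landmark positions**, not on angles: each
(subject, observer, occasion) cell re-perturbs the subject's noiseless
landmarks with independent N(0, σ²) displacements per coordinate. This lets
the two methods' reliabilities differ naturally — Ho's bisector is built
from four points on ~19 mm segments, the new method from two points 30 mm
apart, so Ho's angle carries slightly more noise per mm of placement error.
The default σ = 0.4 mm comes from first-order error propagation: it maps to
roughly 1.1° of angle noise for the chord and 1.2° for the bisector, which
against the ~6–7° between-subject sds puts the simulated ICCs in the
0.90–0.99 band observed for these measurements clinically. No systematic
observer bias is modelled, so simulated interobserver ICCs are about as
high as intraobserver ones; real observers may differ systematically and
show lower between-observer agreement.

Every stochastic operation takes one integer seed and draws from a single
`numpy.random.default_rng` stream in documented order (phantom: six
landmark displacements × 2 coordinates in canonical role order; cohort: the
n × 3 parameter draws in subject order, then ages; observers: subjects
outer, observers middle, occasions inner).

## Reliability statistics

The ICC variant is **two-way random effects, absolute agreement, single
measurement** — ICC(2,1)/ICC(A,1) — for both analyses, with occasions as
columns for intraobserver and observers as columns for interobserver
matrices. The crossed design and the clinical need for absolute (not just
consistency) agreement motivate the choice; every result carries the model
label so the variant is auditable, since one- and two-way forms differ in
the third decimal at these magnitudes. The 95% CI uses the standard
F-distribution construction with Satterthwaite degrees of freedom; in the
MSE = 0 limit (exact agreement up to a column shift) the degrees of freedom
are taken at their analytic limit (n−1)(k−1) so the bounds stay finite.
Interobserver occasion handling defaults to the first occasion
(`occasion_policy="first"`); averaging occasions (`"mean"`) is offered.
Negative estimates are reported as computed, with a warning, never
truncated to zero.

## Study pipeline

The method comparison is a **paired** t-test by default: both methods are
applied to the same vertebrae, so pairing is the defensible reading; an
unpaired variant is available behind a flag. Algebraically the paired t on
(β, α) equals the one-sample t on τ. All tests are two-sided with
significance at p < 0.05. Pearson correlations of τ against β, α, and Cobb
use the t-transform p-value with n − 2 df. The report's mean torsion is
computed as mean(β) − mean(α), so the defining identity holds exactly on
unrounded values. Degenerate inputs (a constant vector, including constancy
up to floating-point jitter from an sd-0 simulation) do not abort the run:
the affected correlation is skipped and logged in the report.

## Problem sizes and numerical choices

Test and verification sizes are chosen so each statistical check has
comfortable Monte-Carlo margin at small cost: 100 phantoms for exact
geometric properties, 10 000 subjects for cohort moment recovery
(standard error of the β mean ≈ 0.07°, tolerance 0.2°), 500 × 3 matrices
for the closed-form ICC check (tolerance 0.02), and 200 replicate cohorts
for the power check of the paired test (power ≈ 1 at effect 6.1°/3.9° with
n = 25, threshold ≥ 95% of runs). Degenerate-geometry thresholds: 1e−12 for
coincident points/zero-length segments, 1e−9 for the antiparallel-bisector
norm.

## Known limitations

- The phantom deforms by rigid sub-rotations only; real apical vertebrae
  also bend, wedge, and remodel, so passing tests demonstrate correctness
  of the geometry and statistics, not robustness to anatomical deformity of
  the landmarks themselves.
- Rotations α and β are relative values in the slice frame; no
  normalization to a sacral/iliac reference is provided, so absolute
  rotations are not comparable across patients — only τ is.
- Apical-level selection and Cobb measurement happen upstream; the package
  takes the level and the Cobb angle as input metadata.
- Observer simulation has no systematic per-observer bias and no
  heavier-tailed blunder component; simulated reliabilities are therefore
  an optimistic bound for real annotation.
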