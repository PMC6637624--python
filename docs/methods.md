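# Methods

`bivatlas` implements a biventricular shape-atlas pipeline of the kind
used to relate cardiac geometry to risk factors in large population
imaging studies: labeled 2D contour stacks from cine CMR are turned into
fitted 3D subdivision-surface heart models, the fitted models into a PCA
shape atlas, and the atlas scores into classifiers and morphometric
z-scores.  Because real imaging data cannot ship with the package, a
synthetic-data generator with exact ground truth is a first-class
component: every downstream stage is validated against quantities the
generator knows by construction.

## The deformable model

The heart model is a coarse labeled quad mesh (the *control mesh*)
refined by Catmull-Clark subdivision, by default twice.  Crease edges are
infinitely sharp (cubic-B-spline curve rules: sharp edge points are edge
midpoints; a vertex with two incident sharp edges uses the 1/8-3/4-1/8
rule; three or more pin the vertex) and sit exactly at the four valve
rings and the two RV insertion lines, where real ventricular geometry has
creases.  Subdivision is linear in the control vertices and is carried
explicitly as a sparse operator `S`; this single design choice makes the
whole fitting stage a sparse linear-algebra problem.

The template is built from paired analytic surfaces so that closed-form
oracles exist:

* LV endocardium: a prolate ellipsoid of revolution (long axis 90 mm,
  radius 26 mm) truncated at 85% of its long axis; the open basal
  boundary is the mitral ring.
* Epicardium: the same ellipsoid offset by the 10 mm wall, closed at the
  base by a planar "valve plane" roof in which two small creased holes
  are the aortic and pulmonary orifices.
* RV: a crescent formed by a second ellipsoidal sheet wrapping 190
  degrees of the septum at a maximal free-wall offset of 34 mm; the
  septal sheet coincides with the epicardium by construction, the open
  top is the tricuspid ring.  Apical openings are closed with quad-grid
  (Coons patch) caps, keeping the mesh all-quads.

Defaults give LV EDV ≈ 111 mL, LV EF ≈ 0.58, RV EDV ≈ 124 mL, RV EF ≈
0.47, LV mass ≈ 140 g — on the scale of an adult population cohort.  The
end-systolic reference is a second template built with contracted
parameters (endocardial radius × 0.70, long axis × 0.85, RV × 0.74, wall
thickened to conserve mid-wall cross-section) and translated so the apex
stays fixed while the base descends ≈ 11 mm — the dominant real systolic
motion (valve-plane excursion).  Both frames share one topology, so every
fitted subject is a vertex-correspondent instance of the same mesh.

The control mesh has 433 vertices and 409 quads; two subdivisions give
6,634 vertices.  The published templates this emulates are of similar
coarse scale but their exact connectivity is not public; no vertex count
of a published model is reproduced, and none needs to be — all
shape-vector arithmetic follows the retention mask.

## Synthetic populations

`sample_population` draws subjects deterministically from a seed
(`numpy` `SeedSequence` spawning, one child stream per subject).  Three
planted modes deform the control vertices:

1. **size** — isotropic scaling about the apex, log-scale SD 0.06;
2. **valve-plane excursion** — extra ES basal descent, SD 2 mm,
   apex-pinned linear ramp;
3. **sphericity** — volume-neutral radial/longitudinal exchange,
   log SD 0.05.

These SDs are the package's study conditions; they produce shape
variance on the order seen in population atlases (mode 1 size, mode 2
valve motion, mode 3 sphericity).  Covariates are drawn at cohort scale
(age ~ N(62, 7.5) yr, height ~ N(170, 9) cm, weight ~ N(76, 15) kg, sex
~ Bernoulli(0.48)) and, by default, mildly couple to the size mode so
that covariate adjustment in the morphometric regression is actually
exercised.  Binary factors are drawn per subject with optional
covariate-dependent prevalence; a factor's effect is a shift of the mode
coefficients and/or a named direct displacement field.

The shipped `septal_shift` preset displaces the septum toward the RV
with compensating free-wall displacements; two scalar amplitudes are
root-found at template-build time so that both cavity volumes are
preserved to better than 0.01% at the 3 mm calibration amplitude.  The
preset is therefore invisible to mass/volume features but visible to
shape features — the scenario in which atlas scores must beat a
mass/volume baseline.

`render_contours` cuts the true surfaces with a short-axis stack (8 mm
spacing, slices from one margin above the apical extreme to one below
the basal extreme, so the slice count is `floor(extent/8) + 1`) and two
long-axis planes (2-chamber and 4-chamber; no LV-outflow-tract view).
Valve points are the ring-plane crossings on LAX views only, plus an RV
apex landmark on the 4-chamber view.  Degradation mirrors acquisition:
one in-plane breath-hold shift per SAX slice (SD 2.5 mm by default,
shared by ED and ES since both frames come from one acquisition) and
isotropic in-plane Gaussian point noise (SD 1 mm by default, emulating
pixel-limited manual contouring).  What the generator does **not**
emulate: image intensities, papillary muscles, atria beyond valve
points, through-plane shift or rotation, observer-specific contouring
styles, and pathology-specific remodeling.  Passing tests therefore
demonstrate correctness of the algorithms under known geometry and
realistic degradation levels — not segmentation robustness on real
images.

## Breath-hold correction

A *stiff* LV fit (smoothing weight ×100) to the LAX contours only gives
a shift-free LV estimate; its intersections with each SAX plane yield
area-weighted model barycentres; a straight 3D axis is fit to these by
total least squares; each slice's contours are translated so the
observed barycentre (LV endocardium, falling back to RV endocardium and
then to the epicardium on slices without LV blood pool) lands on the
axis-plane intersection.  Correction is estimated per frame by default;
a config switch averages ED/ES corrections.  One pass is used (no outer
iteration); on the synthetic cohort the correction is idempotent below
0.2 mm and recovers per-slice shifts with < 1 mm mean absolute error at
2.5 mm shift SD.

## Mesh fitting

Per frame:

1. **Rigid pre-registration.**  The template is posed by Kabsch on
   landmark pairs (valve-ring centroids, RV apex) followed by
   closest-point Kabsch polish on a point subsample, keeping whichever
   pose minimizes the association residual.  Without this step the
   deformation penalties act in template pose and rigid equivariance is
   lost.
2. **Linear fit.**  Closest-point association pairs every contour point
   with its own-label patch (valve points with their ring polyline, the
   apex landmark with the apex vertex); the surface position at each
   association is a sparse row of barycentric weights times `S`.  The
   solve minimizes mean squared residual plus `lambda` times the mean
   squared displacement difference across control edges (graph-Laplacian
   smoothing, the near-affine deformation penalty) plus a `1e-6` ridge
   fixing the translation gauge of data-free components.  `lambda = 1`
   by default: the noiseless self-fit error is < 0.1 mm, while
   `lambda -> infinity` collapses to the translation-only fit.
   Association and solve alternate for 5 outer iterations; the objective
   is non-increasing by construction.
3. **RV epicardium.**  The RV endocardium is offset along area-weighted
   vertex normals by the population-average RV wall thickness — 3 mm at
   ED, 5 mm at ES.  It completes the model and is excluded from all
   analyses.
4. **Constrained refinement.**  L-BFGS on the same objective plus a
   hinge penalty `mu * mean(max(0, d_min - c_i)^2)` on the signed
   LV-endocardium-to-epicardium clearance along the current wall
   direction (`d_min` = 1 mm, `mu` = 10).  A model with non-positive
   clearance at convergence is rejected.  This enforces the observable
   contract of diffeomorphic registration — surfaces do not cross —
   without the unpublished constraint formulation it stands in for.

Numerical notes: quads are split along the shorter diagonal for all
triangle computations; label-restricted triangulations are memoized on
the control mesh, so the split pattern is fixed at the template geometry
and identical across fitting iterations and subjects (deterministic, and
avoids association flicker).  Exact closest-point queries use a
centroid KD-tree with a provably sufficient candidate radius (upper
bound from the k nearest centroids plus the maximal triangle
circumradius), verified against the exhaustive per-triangle oracle to
1e-9 mm.

At the default study conditions (noise SD 1 mm, shift SD 2.5 mm) the
grand-mean point-to-surface error over a 20-subject cohort is ≈ 0.8 mm;
the acceptance bound is 1.5 mm.

## Atlas

Generalized Procrustes alignment of the ED point sets — translation and
rotation only, never scaling, so size remains biological signal — is
iterated to mean-shape convergence (1e-6 mm); each subject's ED
transform is applied verbatim to its ES points, preserving ED→ES motion
in the atlas.  Aortic/pulmonary ring vertices and the valve-plane roof
(vertices with no contour support) are removed by a retention mask
stored inside the atlas; the synthesized RV epicardium never enters a
fitted surface.  The shape vector concatenates aligned ED then ES
coordinates (`P = 6 ×` retained vertices).  PCA is column-mean-centred
SVD with variances ordered non-increasing and a deterministic sign
convention (largest-magnitude loading positive), making serialized
atlases byte-reproducible.  Reconstructions are lifted back onto full
template surfaces by anchoring the excluded basal vertices with a
similarity transform estimated from the retained epicardial rim, so
capped volumes of reconstructed shapes remain well defined.

## Derived measures

Volumes are divergence-theorem integrals of the capped cavity surfaces
(caps are planar triangle fans over the valve rings); LV mass is
(epicardium-enclosed − LV cavity) × 1.05 g/mL.  The echo-style ratios
need 3D operationalizations, chosen deterministically:

* septal plane: least-squares plane through the RV septal patch,
  oriented toward the free wall;
* mid-ventricle: 50% of the base-apex axis; bands of ±15-20% are used
  where a sector of vertices is needed;
* RV sphericity: tricuspid-centroid-to-apex length over the maximal
  distance from mid-ventricular free-wall vertices to the septal
  *surface* (nearest point).  Measuring to the septal plane instead is
  biased for strongly wrapped septa and breaks the expected inverse
  proportionality to the free-wall offset;
* eccentricity: maximal cavity chords parallel/perpendicular to the
  septal-plane trace on the mid-ventricular cross-section (101-offset
  line sweep, validated against a dense sweep);
* relative wall thickness: twice the mean endo-epi distance over the 60
  degree sector opposite the RV, divided by the maximal mid-cavity chord
  along the septum-posterior axis;
* LV longitudinal shortening mirrors the RV definition via the mitral
  centroid and LV apex.

All ratios are rigid-motion invariant and scale invariant; volumes scale
with the cube.  Every measure is a pure function of the model.

## Risk models

For each factor, positives are factor-positive subjects minus those with
previous MI or angina (for angina only MI-positives are removed; for
previous MI nobody), negatives are the reference group (here: subjects
with no positive factor).  Classification uses elastic-net logistic
regression (mixing parameter 0.5, penalty strength by inner 5-fold CV
over a log grid, features standardized within each training fold) under
stratified 10-fold CV.  Covariates are excluded from classification —
the question is what geometry alone carries — but included in the
morphometric-mode regression.  The averaged ROC is the vertical mean of
the per-fold empirical ROCs on a fixed 1001-point FPR grid using
right-continuous step interpolation (linear interpolation systematically
underestimates near FPR 0; a separable problem must score AUC 1).
Operating points use the Youden index with ties broken toward higher
specificity.  Correlated AUCs are compared with DeLong's
placement-value test; a model compared with itself returns p = 1.

Morphometric modes: each of the M mode scores is regressed (OLS) on
[intercept, age, sex, height, all factor indicators]; a factor's mode is
its coefficient vector across components; positive/negative mean shapes
push the cohort-mean design row with the factor set to 1/0 through the
fitted models; z-scores standardize projections onto the unit mode
direction against the reference group (in-sample reference statistics).
Displacement maps project the positive-negative difference on the
negative shape's outward normals, with the septal sign flipped so that
positive always means "toward the RV" (outward from the LV).

## Problem sizes and the truth-based cohort shortcut

The full imaging pipeline (render → correct → fit) costs a few seconds
per subject, so pipeline-level claims (fitting error, shift recovery)
are evaluated on 20-subject cohorts, while atlas- and association-level
claims use 500-600 subjects built directly from the generator's
ground-truth surfaces plus 0.5 mm control-vertex jitter emulating
residual fit error (`pipeline.models_from_truth`).  This keeps each
analysis at the sample size that claim needs: the fitting stage is
validated on its own cohorts, and the statistical machinery sees
realistic-sized cohorts without paying the fitting cost 600 times.

## Known limitations

* The template is analytic and smooth; real hearts have trabeculation,
  papillary muscles and outflow tracts the model does not represent.
* The epicardium models the LV epicardium only; the RV free-wall
  epicardium exists solely as the offset construction used during
  fitting.
* The RV septal sheet coincides with the epicardium, so nearest-patch
  label attribution between those two surfaces is inherently ambiguous
  (they are the same wall).
* Slice correction assumes a straight long axis and in-plane shifts
  only; no rotation or through-plane correction.
* Eccentricity chord searches use a finite offset sweep (1% accuracy);
  caps are planar fans (exact only for planar rings).
* Elastic-net hyperparameters follow field defaults (mixing 0.5); no
  claim is made that they are optimal for any particular cohort.
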