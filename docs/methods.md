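# Methods

This note documents the models, conventions and numerical choices behind
the package, in the spirit of a model-description appendix: what is
computed, under which assumptions, and where the behaviour is a design
choice rather than a forced consequence of the method.

## Anatomical frame and alignment

Limb meshes are expressed in a landmark-anchored frame: origin at the
midpoint of the medial and lateral humeral epicondyles; x along the
epicondyle axis, positive toward lateral; y anterior–posterior with the
olecranon on the negative (posterior) side; z longitudinal, increasing
distal → proximal; axes orthonormal and right-handed. The epicondyle
midpoint is the natural origin because the epicondyles are the stable,
palpable landmarks that also anchor socket suspension. Left limbs are
mirrored about the sagittal plane into this canonical right-side frame
(triangle winding flipped to keep normals outward) so retrieval can
compare across sides; the flag `mirror_left` disables this. Because the
mirror is a reflection, the full alignment map of a left limb has
determinant −1 and is reported as a 4×4 matrix, while the rigid part is
kept as a proper rotation + translation.

Socket registration follows the clinical convention: the longitudinal
axis is the principal axis of the socket's vertex cloud, oriented from
the distal tip toward the proximal trimline; the transverse plane (z = 0)
is placed at the height of the deepest trimline indent — the lateral
epicondyle seat — and the rotation about z is fixed by requiring the
olecranon obturator centre (or olecranon tip) to lie in the sagittal
plane on the posterior side. On an exactly mirror-symmetric socket this
recovers the generating frame to machine precision; trimline asymmetries
(unequal epicondylar indents) tilt the principal axis by a fraction of a
degree, i.e. ≲0.2 mm at the socket rim. In clinical data the two
reference points are manual annotations; the synthetic generator emits
them exactly.

ICP refinement is the point-to-point variant: centroid pre-alignment,
nearest-neighbour correspondences from a k-d tree, Kabsch update,
stopping when the relative change of the mean squared residual falls
below `icp_tol` (default 1e-6) or after `icp_max_iter` (default 100)
iterations. The residual is monotone non-increasing by construction.

## Retrieval and scaling

Shape similarity is the mean nearest-neighbour Euclidean distance between
surface point clouds, evaluated one-directionally from the query to the
library limb (a symmetric average is available behind a flag). Each
library limb is first isotropically rescaled so its proximal–distal
length (z-extent of the aligned mesh) matches the query; this removes
size, the dominant mode of limb variation, so the comparison is of shape.
Ties are broken toward the scaling factor closest to 1 (least geometric
distortion), then lexicographic id.

The anterior–posterior and medio-lateral dimensions used for anisotropic
refinement are whole-mesh caliper extents along the frame's y and x axes.
This is deliberate: extents are deterministic, robust to local surface
detail, and frame-dependent — measuring them only makes sense after
alignment. A per-slice alternative (widest cross-section) is exposed in
the configuration. Anisotropic scaling is applied about the frame origin
with z untouched, so the refinement step cannot undo the length match.

### Sampling policy

One configured seed drives every surface-sampling call. Sampling is
area-weighted and deterministic per (mesh, n, seed), so comparing a mesh
against itself pairs identical clouds and yields exactly zero distance;
self-identity checks are therefore exact rather than sampling-limited.
Between *different* clouds the distance carries a discretization floor of
roughly half the mean sample spacing (≈0.5 mm at n = 10,000 on a
forearm-sized socket); distances below that floor are not meaningful.
Default n = 10,000 points per mesh balances that floor against runtime.

## Global evaluation

* **Surface deviation** — both sockets are sampled, co-registered
  (centroid + ICP), and the mean nearest-neighbour distance from
  prediction to reference is reported, making the measure invariant to
  moderate initial misalignment.
* **Volume difference** — volumes come from a voxel grid at `voxel_pitch`
  (default 0.5 mm): boundary loops are capped with centroid fans, then
  voxel centres are classified inside/outside layer by layer using the
  chord-closed cross-section polygons under the even-odd rule. Counting
  centres makes the estimate unbiased in the pitch (measured ≤0.2 % error
  on cylinders/cones at 0.5 mm). The signed difference is
  100·(V_pred − V_ref)/V_ref, so negative means the prediction is
  smaller; the absolute value feeds the fit bands (≤5 % good, ≤10 %
  acceptable, else replace; boundaries go to the better class).
* **CSA profile** — 100 stations at fractions (j + 0.5)/100 of each
  socket's *own* z-extent, from distal tip to trimline top, paired by
  fraction so the profile is invariant to overall length. Stations whose
  reference area is below 1 mm² are flagged unstable instead of returned:
  near the distal tip, tiny denominators turn millimetre discrepancies
  into arbitrarily large percentages.

Open cross-section contours (e.g. across the olecranon cutout) are closed
with the straight chord between their endpoints — a deterministic,
conservative convention for three-quarter socket designs.

## Local evaluation

The signed distance field is sampled on the predicted socket; the sign at
each point comes from the outward normal of the nearest reference sample
(positive = prediction outside/larger). Pronounced deviations use the
mean-split rule: the mean of the positive values and the mean of the
negative values act as the two thresholds, and points beyond them are
flagged. Flagged points are clustered with DBSCAN separately per sign,
since a deviation region represents one action (material added or
removed).

DBSCAN's neighbourhood radius defaults to
`max(0.025 · socket z-length, 3 · sqrt(area / n))` with
`min_samples = 20`. The first term keeps the clustering size-invariant;
the floor of three mean sample spacings guarantees that a contiguous
flagged patch at the global sampling density can form core points — with
a purely scale-relative eps, realistic sample counts starve the
clustering entirely. Cross-participant aggregation divides region
centroids by each participant's socket z-length, pools them, re-clusters
(eps 0.08, min_samples 2 in normalized space), and summarizes each pooled
cluster by the renormalized mean of the member unit direction vectors
from the anatomical origin, with per-axis SDs. Region names
(anterior-distal trimline, A–P compression, distal tip, supracondylar
compression) are advisory labels assigned by the nearest canonical
direction from a bundled table.

Threshold-tail fragments — small clusters a few dozen points strong at
the rim of a genuine deviation — are a known artifact of the mean-split
rule; recovery analyses use the dominant region per participant and sign.

## Subgroup statistics

Welch's unequal-variance t-test compares the two global outcomes (signed
volume difference, mean L2) across each binary factor: sex, limb shape
(conical/cylindrical), length class (short/very short), and age group
with the pediatric cutoff at 18 years. Age is additionally treated as a
continuous covariate via Pearson's r against both outcomes. The family is
exactly these 10 tests, corrected with Holm–Bonferroni; a factor level
with fewer than 2 members makes its test non-estimable and shrinks the
family. The *signed* volume difference is the outcome (not its absolute
value) so directional biases — undersizing one subgroup, oversizing
another — remain visible. Two zero-variance groups with equal means
return t = 0, p = 1 rather than a division error.

## Synthetic cohort generator

Limbs are surfaces of revolution with elliptical cross-sections
(proximal semi-axes a₀, b₀) and a cosine-blended radius profile ρ(t)
running from 1 proximally to the taper ratio distally; bulbous limbs add
a raised-cosine distal bulge. Landmarks sit on the proximal rim
(epicondyles at ±x, olecranon posterior), end rings are noise-free so the
z-extent equals the nominal length exactly, and optional radial Gaussian
noise (default SD 0.1 mm, the scale of scanner noise) perturbs interior
rings. This is the minimal parameterization that still exercises
conical/cylindrical/bulbous retrieval, anisotropic extents and slicing.

Sockets are derived from the limb surface itself: the angular radius
profile is recovered by slicing the mesh (so any star-shaped limb works),
offset outward by a radial clearance (default 2 mm), extended distally by
a rounded end relief (drawn from 2–6 mm across a cohort — the
subject-specific distal relief is the deliberately variable element),
cut proximally at a trimline whose lateral epicondylar indent dips to
exactly z = 0, and pierced by a posterior olecranon cutout (faces removed
inside a 70°-wide window; the unreferenced vertices are kept so the
obturator-centre reference stays anchored to mesh coordinates). Planted
deviation patches are raised-cosine bumps along a unit direction from the
anatomical origin, giving local-deviation recovery tests an exact target.

Cohort draws are moment-matched to the bundled 19-participant reference
demographic table: lengths from a normal with mean 76.3 mm and SD
23.4 mm truncated to [35, 125] mm; a pediatric/adult age mixture (9:10);
sexes near-balanced; shape classes mostly conical/cylindrical (10:9).
The length-class labels use a documented stand-in cutoff (< 60 mm very
short, ≥ 130 mm long) because the clinical labeling rule depends on the
intact-forearm proportion, which the generator does not model.

What the generator does *not* emulate: soft-tissue asymmetry, scanning
trim irregularities, prosthetist-specific rectifications beyond the
parametric clearance/relief/trimline/cutout family, and real
limb-to-socket covariance. Passing tests therefore demonstrate that the
pipeline's geometry, retrieval and statistics behave correctly and
recover planted ground truth — not that prediction errors on clinical
scans will match the synthetic cohort's values.

## Problem sizes and determinism

Default analyses use n = 10,000 surface samples, 100 CSA stations, and a
1.0 mm voxel pitch for batch leave-one-out runs (0.5 mm for single-pair
volume checks); a 19-participant leave-one-out completes in about two
minutes on one CPU at those sizes. All randomness flows from explicit
seeds: cohort generation, surface sampling and every statistical
simulation are bitwise reproducible per seed, and batch reports embed the
fully resolved configuration.

## Known limitations

* Retrieval identifiability: in a continuous shape population, a strongly
  anisotropically distorted limb can legitimately sit closer to a
  shape-similar neighbour than to its own source, so planted-factor
  recovery is only defined conditional on self-retrieval (observed in
  ~70–90 % of trials at ±10 % planted anisotropy on a 19-entry cohort).
* The retrieval distance is evaluated between point clouds, not
  point-to-surface; its discretization floor (~0.5 mm at n = 10,000)
  bounds how finely near-duplicate limbs can be ranked.
* Socket registration assumes an elongated, roughly axis-symmetric
  socket; heavily asymmetric trimlines tilt the principal axis slightly.
* The subgroup analysis is exploratory by construction: 10 tests on small
  cohorts, Holm-corrected; it makes no causal claims.
* Automatic detection of landmarks or the trimline indent from raw scans
  is out of scope; these are inputs.
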