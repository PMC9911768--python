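# Methods

`bivatlas` replicates, end to end, an atlas-based analysis of biventricular
shape in repaired tetralogy of Fallot (rTOF): whether regional features of
end-diastolic (ED) shape discriminate patients referred for pulmonary valve
replacement (PVR) from those who were not, better than the standard imaging
indices used clinically. Because the cross-sectional CMR-derived meshes such
an analysis runs on are not redistributable, the package pairs the analysis
with a synthetic cohort generator whose ground truth is analytic, so every
stage is testable without any external data.

## Data model

A subject is a pair of corresponded, labeled triangulated surfaces (ED and
end-systole, ES). Vertices carry one of three surface labels — LV
endocardium, RV endocardium, epicardium — and the four valve annuli
(mitral, tricuspid, aortic, pulmonary) are the only boundary rings of those
sub-surfaces. Vertex count and ordering are identical across the cohort
(point correspondence), which is what makes coordinate-level PCA meaningful.
Units are fixed: coordinates mm, volumes mL, masses g, indexed values per
m² of body surface area (BSA).

## Imaging indices

Cavity and wall volumes are measured by numerical integration: each labeled
sub-surface is closed by capping its annulus rings with triangle fans to the
ring centroids (the simplest deterministic closure; the choice only affects
volumes by the small cap region) and the signed-tetrahedron sum gives the
enclosed volume. Ejection fraction is `100·(EDV−ESV)/EDV`; masses use a
myocardial density of 1.05 g/mL, the standard CMR literature value. The
LV/RV wall split cuts the closed epicardial shell at the wall interface
plane, with the interventricular septum assigned to the LV; the plane is
part of the mesh metadata when the generator emits it and is otherwise
estimated from the vertex-level wall-assignment map (accuracy then limited
to roughly half the mesh spacing). The clipped side's volume is integrated
with signed tetrahedra about a reference point *in* the cutting plane, which
makes the open cut contribute exactly zero. PRVi and PRF are
flow-derived quantities and are carried as inputs from the subject table.
The ten indices (LV/RV EDVi, ESVi, EF, Mi, PRVi, PRF) deliberately match
the shape-mode feature-set size.

## Shape atlas

Subjects' ED surfaces are aligned by generalized rigid registration:
iterate "align all to the current mean (Kabsch, rotation + translation
only), recompute the mean" until the mean moves less than 1e-6 mm per
vertex (max 20 iterations; non-convergence is recorded and the last iterate
used; the first subject seeds the reference). Scaling is deliberately not
removed — heart size is physiology, and body size is instead controlled as
a regression covariate. PCA runs on the stacked 3N coordinate vectors via
the subject-space Gram matrix; eigenvalues below 1e-10 of the largest are
degenerate. A subject's morphometric Z-score on a mode is its projection
divided by the mode's population SD, so Z-score columns have unit sample SD
by construction. Mode signs are fixed (largest-magnitude coordinate
positive) for reproducibility.

Mode subset selection mirrors the clinical-feature count: modes within the
95% cumulative-variance cut are ranked for predicting PVR status by a
Pearson chi-square test of quantile-binned Z-scores (10 bins, empty bins
merged; importance = −log10 p; ties prefer the lower mode index), and the
top ten retained. On synthetic cohorts the 95% cut usually keeps ~8–15
modes — fewer than the ~30 seen on real cohorts — because the planted shape
variation is low-dimensional by construction.

## Associations and group statistics

Associations with PVR status are ordinary least squares per response
(each imaging index; each selected mode's Z-scores), with PVR status, sex
and repair type dummy-coded (references: No-PVR, female, transannular
patch), time after repair continuous, and BSA continuous for shape-mode
responses only (indices are already BSA-indexed). All continuous variables
including the response are z-normalized first, and the reported association
is the two-sided p-value of the PVR coefficient. Group summaries use a
Shapiro-Wilk gate at α = 0.05 per group to choose between the unpaired
t-test and the Wilcoxon rank-sum test; categorical tables use Pearson's
chi-square without continuity correction. Significance is 0.05 throughout.

## Clustering and the criteria comparator

Features with PVR p < 0.05 are retained per set; a set with fewer than two
significant members is padded with the next-lowest-p feature to meet the
two-variable minimum clustering needs. Cosine k-means (k = 2; Lloyd
iterations on row-normalized features, centroids renormalized each step,
emptied clusters reseeded at the farthest point; best of 50 restarts, or an
exhaustive sweep of all point-pair initializations for cohorts of ≤16)
splits the cohort; each cluster predicts its dominant group, and the 2×2
matching matrix is scored by the Matthews correlation coefficient, with
sensitivity and specificity reported alongside. The cosine metric is chosen
to ignore absolute measurement sizes and compare only their pattern. The
same clustering is repeated on the asymptomatic subset. The comparator is a
deterministic threshold rule — RV EDVi > 160 mL/m², RV ESVi > 80 mL/m²,
RV EF < 47%, LV EF < 55%, with symptomatic patients needing one positive
criterion and asymptomatic two; the volume thresholds are the commonly
cited referral cut-offs, while the EF thresholds and count rule are package
defaults and configurable.

Note one known property of the padding rule: under a true null (no group
effects anywhere) the retained features are still the *least insignificant*
ones, i.e. selected on the same labels the clustering is later scored
against. This double-dipping biases null MCCs upward (typically ~0.1–0.3
rather than ~0.1); the acceptance suite measures the pipeline exactly as it
runs.

## Geometric strain

Longitudinal and circumferential strains are Cauchy strains of arc length
(`100·(L_ES−L_ED)/L_ED`) on the endocardial structured parameterization:
longitudinal lines run apex pole → basal ring along each meridian,
circumferential lines are the closed rings; per-line strains are averaged
unweighted. The septum is part of the LV endocardial surface and therefore
included in LV strains. Radial strain uses a modified centerline method on
a short-axis stack (planes perpendicular to the LV long axis — the mitral
annulus plane normal — at 10–90% of the apex-base extent, 8 slices):
endo and epi plane contours are restricted to the ventricle's free-wall
sector (±100° about the direction away from the other ventricle, because
the epicardium wraps both ventricles and septal chords to it would cross
the opposite cavity), resampled to 100 equal arc-length stations, and wall
thickness is the chord along the centerline (midpoint-curve) normal between
the endo and epi crossings. Per slice, thickness is averaged over stations
*before* the Cauchy ratio: per-station ratios on a 2–3 mm RV wall with
realistic vertex noise carry a large positive Jensen bias (noise in the
denominator), while slice-mean ratios are unbiased. All constructions are
relative to the mitral plane and contour centroids, so strains are
invariant to a common rigid transform of the pair.

## Synthetic cohort generator

The generator emulates the study conditions — 48 PVR / 36 No-PVR — and is
the package's study-condition definition, not a tuning surface.

**Template.** All surfaces share a flat base plane (z = 0), apex down. The
LV endocardium is a half prolate spheroid; the RV endocardium a
septally-flattened half spheroid (polar radius `r(1+β cos θ)`, flat side
toward the LV) whose long axis tilts toward the LV with depth (the largest
collision-free slope), as real RV apexes do; cross-section areas are
shear-invariant so cavity volumes stay closed-form. The epicardium is a
tapered capsule: at each depth, the convex hull of an LV disk and an RV
disk that circumscribe the endocardial sections with free-wall clearances
`t_lv`, `t_rv`. Its volume and the wall split (a plane tilted with the RV
axis, septum to the LV) are evaluated by quadrature of the closed-form
cross sections (~1e-4 relative). The basal plate is flat with two circular
holes — the aortic and pulmonary annuli — so closing any sub-surface with
flat caps recovers the continuous region's volume exactly.

**Per-subject shape.** Height/weight (hence Mosteller BSA), ages, sex,
repair type, symptoms and PR measures are drawn per group from
distributions matched to the reported cohort summaries (the No-PVR
symptomatic proportion is unreported; default 0.1). The template is scaled
by (BSA/1.6)^(1/3), ventricular radii are solved for drawn EDVi targets,
and the epicardial clearances are solved (chord Newton on the quadrature
volumes) for drawn mass-index targets. The RV mass floor of the capsule
(the circumscribing clearance plus the inter-ventricular bridge) is
~41 g/m², so RV Mi realizes slightly above its ~40 g/m² target — a known
limitation of the phantom.

**Systole.** ES is the template re-evaluated with per-ventricle
circumferential and longitudinal scales: cavity volumes scale exactly by
λc²·λl, so drawn EF targets are hit exactly, and λl is root-found so the
continuous-meridian longitudinal strain hits its drawn target. The RV
translates toward the LV through systole so the septum thickens in
proportion to the LV free wall. Epicardial thickening has two modes:
`prescribed` (default) solves the clearances so the analytic mean free-wall
thickness thickens by drawn radial-strain targets; `incompressible`
conserves each side's wall volume exactly instead (radial strain is then
implied — and exaggerated for the thin RV wall, which is why it is not the
default). Strain ground truth (LS by meridian quadrature, CS exactly
λc−1, RS by analytic radial-ray thickness over the same slice stack and
free-wall sectors) is emitted per subject.

**Population structure.** Five named, mutually near-orthogonal (|cos| <
0.2), rigid-motion-free deformation fields — RV apical dilation, RV basal
bulge, LV dilation, LV conicity, pulmonary-annulus dilation — are planted
with per-group mean offsets whose default directions and ~0.35–0.7 SD
magnitudes follow the reported mode associations (PVR: basal bulge, LV
dilation/conicity, PV dilation; No-PVR: apical dilation). The fields are
applied identically to ED and ES (so they perturb measured strains only at
second order), then i.i.d. vertex noise (0.6 mm, a realistic
surface-registration error) and a random rigid misalignment (±10°,
±10 mm, shared by the pair) are added. All draws flow from one seed
through named substreams; cohorts are bit-reproducible.

Two canonical condition variants exist for validation: a
*strongly-separated* cohort (per-field offsets ±1.25 SD, calibrated so
that after PCA's mixing of the planted directions the *selected* atlas
modes separate the groups by ~2 SD; confounders matched between groups so
body size does not masquerade as shape signal) and a *null* cohort (all
group distributions identical, zero planted offsets).

**What the generator does not emulate.** Anatomical fidelity (real
trabeculated RV geometry, valve orientation, outflow tracts), imaging
physics, segmentation bias, or inter-subject topology differences. Passing
tests demonstrate that the *analysis machinery* is correct and calibrated
on data with the study's statistical structure; they do not validate
clinical conclusions on real meshes.

## Numerical choices

Alignment tolerance 1e-6 mm, max 20 iterations; PCA degeneracy 1e-10 of
the largest eigenvalue; chi-square binning 10 quantile bins; k-means
restarts 50 with a mandatory seed; capsule quadrature 64 depth levels ×
160-point polygons; epicardial solves use a chord-Newton with one
finite-difference Jacobian (the volume–clearance map is near-linear);
meridian quadrature uses Simpson on 201 nodes. Default mesh resolution is
16 rings × 24 meridians per ventricle (20 × 32 epicardial) — fine enough
that cavity volumes are within ~1.5% of closed forms and arc-length
strains are exact to <0.1%, while radial strain of the thin (~2–3 mm) RV
free wall retains a discretization error up to ~12 percentage points
(polygon inscription is a visible fraction of that wall); the error
shrinks with resolution and is verified to do so in the tests.

## Known limitations

- RV mass index floors at ~41 g/m² (capsule filler), biasing RV Mi high.
- RV radial strain at default resolution carries the discretization error
  noted above; LV radial strain is accurate to <1 pp.
- The analytic per-subject volume/strain truth refers to the parametric
  base shape; planted shape variance and noise scatter mesh-measured
  values around it by design.
- Under a true null, the two-variable padding rule makes reported MCCs a
  biased (upward) measure of discrimination, as documented above.
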